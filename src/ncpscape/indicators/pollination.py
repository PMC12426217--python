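"""Pollination (POL): pollinator abundance supply, crop-dependence demand.

Supply follows the classic nesting-resource x foraging-weighted floral
resource formulation: abundance at a pixel is its nesting suitability times
the exponential-kernel average of floral resources around it. Demand is the
pollinator-dependent share of cropland, rescaled by the maximum attainable
dependence. Both are [0, 1] indices averaged per municipality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import (
    LAND_COVER_CLASSES,
    LC_CODE,
    ConfigurationError,
    EconTables,
    KernelParams,
    LandscapeStack,
)
from ..zonal import zone_mean, zone_sum
from .kernels import exponential_kernel, kernel_average


@dataclass(frozen=True)
class PollinationLookups:
    """Nesting suitability N and floral resource F per land-cover class."""

    nesting: dict[str, float] = field(
        default_factory=lambda: {
            "settlement": 0.1,
            "cropland": 0.2,
            "horticulture": 0.3,
            "forest": 0.7,
            "meadow_pasture": 0.6,
            "water": 0.0,
            "park_public": 0.4,
            "other": 0.3,
        }
    )
    floral: dict[str, float] = field(
        default_factory=lambda: {
            "settlement": 0.2,
            "cropland": 0.4,
            "horticulture": 0.6,
            "forest": 0.5,
            "meadow_pasture": 0.9,
            "water": 0.0,
            "park_public": 0.7,
            "other": 0.3,
        }
    )


def _lookup_raster(land_cover: np.ndarray, table: dict[str, float]) -> np.ndarray:
    missing = [c for c in LAND_COVER_CLASSES if c not in table]
    if missing:
        raise ConfigurationError(f"lookup missing land-cover classes {missing}")
    lut = np.array([table[c] for c in LAND_COVER_CLASSES])
    return lut[land_cover]


def pollinator_abundance(
    land_cover: np.ndarray,
    pixel_size: float,
    params: KernelParams,
    lookups: PollinationLookups,
) -> np.ndarray:
    """Per-pixel pollinator abundance index in [0, 1]."""
    nesting = _lookup_raster(land_cover, lookups.nesting)
    floral = _lookup_raster(land_cover, lookups.floral)
    kernel = exponential_kernel(
        params.foraging_distance_alpha, params.truncation_radius, pixel_size
    )
    return np.clip(nesting * kernel_average(floral, kernel), 0.0, 1.0)


def pollination_supply(
    stack: LandscapeStack,
    t: int,
    params: KernelParams | None = None,
    lookups: PollinationLookups | None = None,
) -> np.ndarray:
    """Mean pollinator abundance per municipality at timestep ``t``."""
    params = params or KernelParams()
    lookups = lookups or PollinationLookups()
    abundance = pollinator_abundance(
        stack.land_cover[t], stack.pixel_size, params, lookups
    )
    return zone_mean(abundance, stack.zones, stack.n_zones)


def pollination_demand(
    stack: LandscapeStack, t: int, econ: EconTables
) -> np.ndarray:
    """Pollinator-dependence index of each municipality's cropland.

    Demand = sum over crop classes of (area share within the municipality's
    total cropped area) x (dependence fraction), rescaled by the maximum
    dependence across crop classes so the index reaches 1 when all cropland
    is in the most dependent class. Municipalities without cropland score 0.
    """
    if not econ.crop_pollinator_dependence:
        raise ConfigurationError("no crop pollinator-dependence fractions defined")
    lc = stack.land_cover[t]
    n = stack.n_zones
    weighted = np.zeros(n)
    crop_area = np.zeros(n)
    for crop_class, dependence in econ.crop_pollinator_dependence.items():
        if crop_class not in LC_CODE:
            raise ConfigurationError(f"unknown crop class {crop_class!r}")
        area = zone_sum((lc == LC_CODE[crop_class]).astype(float), stack.zones, n)
        weighted += dependence * area
        crop_area += area
    max_dep = max(econ.crop_pollinator_dependence.values())
    demand = np.zeros(n)
    has_crops = crop_area > 0
    if max_dep > 0:
        demand[has_crops] = weighted[has_crops] / crop_area[has_crops] / max_dep
    return np.clip(demand, 0.0, 1.0)
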