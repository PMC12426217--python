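"""Recreation (REC): usable recreation space supply, walk-distance demand.

Supply combines three feature layers — a land-cover recreation value, a
water-proximity bonus, and a public-park flag — into a per-pixel value
v in [0, 1] (weighted average; the land-cover layer carries most weight,
water and parks act as bonuses); pixels at or above a threshold contribute
v x pixel area x a usable-space fraction, and the municipal figure is the
zone mean of those contributions (m2 per pixel). Demand is the per-capita
recreation need applied to the population within walking distance of each
pixel, averaged per municipality (same m2-per-pixel scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from ..types import LAND_COVER_CLASSES, LC_CODE, ConfigurationError, LandscapeStack
from ..zonal import zone_mean
from .kernels import disk_kernel, kernel_average


@dataclass(frozen=True)
class RecreationConfig:
    threshold: float = 0.4  # minimum pixel value v to count as recreation space
    usable_fraction: float = 0.5  # share of the pixel actually usable
    walk_radius: float = 1000.0  # m, recreation catchment around each pixel
    water_proximity_distance: float = 500.0  # m, distance granting the water bonus
    #: weights of the (land-cover value, water proximity, park flag) layers
    layer_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("recreation threshold must be in (0, 1)")
        if not (0.0 < self.usable_fraction <= 1.0):
            raise ConfigurationError("usable_fraction must be in (0, 1]")
        if abs(sum(self.layer_weights) - 1.0) > 1e-9 or min(self.layer_weights) < 0:
            raise ConfigurationError("layer_weights must be non-negative and sum to 1")


def recreation_value(
    stack: LandscapeStack,
    t: int,
    config: RecreationConfig,
    value_by_class: dict[str, float],
) -> np.ndarray:
    """Per-pixel recreation value: weighted mean of the three feature layers."""
    missing = [c for c in LAND_COVER_CLASSES if c not in value_by_class]
    if missing:
        raise ConfigurationError(f"recreation values missing classes {missing}")
    lc = stack.land_cover[t]
    lut = np.array([value_by_class[c] for c in LAND_COVER_CLASSES])
    class_layer = lut[lc]
    water_mask = lc == LC_CODE["water"]
    if water_mask.any():
        dist = distance_transform_edt(~water_mask) * stack.pixel_size
        water_layer = (dist <= config.water_proximity_distance).astype(float)
    else:
        water_layer = np.zeros_like(class_layer)
    park_layer = (lc == LC_CODE["park_public"]).astype(float)
    w_class, w_water, w_park = config.layer_weights
    return w_class * class_layer + w_water * water_layer + w_park * park_layer


def recreation_supply(
    stack: LandscapeStack,
    t: int,
    config: RecreationConfig | None = None,
    value_by_class: dict[str, float] | None = None,
) -> np.ndarray:
    """Mean usable recreation space per municipality (m2 per pixel)."""
    config = config or RecreationConfig()
    if value_by_class is None:
        from ..synth.region import default_econ_tables

        value_by_class = default_econ_tables().recreation_value_by_class
    v = recreation_value(stack, t, config, value_by_class)
    contribution = np.where(
        v >= config.threshold, v * stack.pixel_area * config.usable_fraction, 0.0
    )
    return zone_mean(contribution, stack.zones, stack.n_zones)


def recreation_demand(
    stack: LandscapeStack,
    t: int,
    config: RecreationConfig | None = None,
    per_capita_need: float = 30.0,
) -> np.ndarray:
    """Mean walk-distance recreation need per municipality (m2 per pixel).

    Per pixel: (population within the walking radius, normalized by the
    buffer pixel count) x per-capita need; a spatially uniform population p
    therefore demands exactly p x need everywhere.
    """
    config = config or RecreationConfig()
    kernel = disk_kernel(config.walk_radius, stack.pixel_size)
    mean_pop = kernel_average(stack.population[t], kernel)
    return zone_mean(mean_pop * per_capita_need, stack.zones, stack.n_zones)
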