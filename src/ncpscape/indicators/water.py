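"""Water regulation (WAT): Budyko-curve water yield supply, consumption demand.

Supply uses the Fu form of the Budyko curve: with aridity phi = PET/P,

    AET/P = 1 + phi - (1 + phi^omega)^(1/omega)

so annual yield Y = P - AET (mm), with a land-cover-specific omega
(vegetated surfaces retain more water, larger omega). Municipal supply is
the zone-mean yield converted to m3 over the zone area. Demand sums
household consumption (per-capita rate x population) and sectoral per-pixel
rates by land-cover class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..types import LAND_COVER_CLASSES, LC_CODE, ConfigurationError, EconTables, LandscapeStack
from ..zonal import zone_counts, zone_mean, zone_sum

logger = logging.getLogger(__name__)

_VEGETATED = ("cropland", "horticulture", "forest", "meadow_pasture", "park_public")


@dataclass(frozen=True)
class WaterConfig:
    """Budyko-Fu omega per land-cover class (default: 2.6 vegetated, 2.0 else)."""

    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {
            c: (2.6 if c in _VEGETATED else 2.0) for c in LAND_COVER_CLASSES
        }
    )

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.omega_by_class.values()):
            raise ConfigurationError("Budyko omega must be > 0")


def budyko_fu_yield(
    precipitation: np.ndarray, pet: np.ndarray, omega: np.ndarray | float
) -> np.ndarray:
    """Annual water yield (mm) from Fu's equation; P <= 0 yields 0."""
    p = np.asarray(precipitation, dtype=float)
    pet = np.asarray(pet, dtype=float)
    yield_mm = np.zeros_like(p)
    valid = p > 0
    if not valid.all():
        logger.warning(
            "%d pixels with non-positive precipitation treated as zero yield",
            int((~valid).sum()),
        )
    phi = np.divide(pet, p, out=np.zeros_like(p), where=valid)
    om = np.broadcast_to(np.asarray(omega, dtype=float), p.shape)
    aet_over_p = 1.0 + phi - (1.0 + phi**om) ** (1.0 / om)
    yield_mm[valid] = ((1.0 - aet_over_p) * p)[valid]
    return np.clip(yield_mm, 0.0, None)


def water_supply(
    stack: LandscapeStack, t: int, config: WaterConfig | None = None
) -> np.ndarray:
    """Annual water yield per municipality (m3).

    Zone-mean yield (mm) x zone area (m2) x 1e-3 (1 mm over 1 m2 = 1 litre).
    """
    config = config or WaterConfig()
    missing = [c for c in LAND_COVER_CLASSES if c not in config.omega_by_class]
    if missing:
        raise ConfigurationError(f"omega_by_class missing classes {missing}")
    lut = np.array([config.omega_by_class[c] for c in LAND_COVER_CLASSES])
    omega = lut[stack.land_cover[t]]
    yield_mm = budyko_fu_yield(stack.precipitation, stack.pet, omega)
    mean_mm = zone_mean(yield_mm, stack.zones, stack.n_zones)
    zone_area_m2 = zone_counts(stack.zones, stack.n_zones) * stack.pixel_area
    return mean_mm * zone_area_m2 * 1e-3


def water_demand(stack: LandscapeStack, t: int, econ: EconTables) -> np.ndarray:
    """Annual water consumption per municipality (m3).

    Household term (per-capita rate x population) plus per-pixel sectoral
    rates summed over the zone.
    """
    lc = stack.land_cover[t]
    n = stack.n_zones
    population = zone_sum(stack.population[t], stack.zones, n)
    demand = econ.per_capita_water_demand * population
    for sector_class, rate in econ.sectoral_water_demand.items():
        if sector_class not in LC_CODE:
            raise ConfigurationError(f"unknown sector class {sector_class!r}")
        demand += rate * zone_sum(
            (lc == LC_CODE[sector_class]).astype(float), stack.zones, n
        )
    return demand
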