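"""Food (FOD): crop + livestock production supply, consumption demand (kg)."""

from __future__ import annotations

import numpy as np

from ..types import LC_CODE, ConfigurationError, EconTables, InputError, LandscapeStack
from ..zonal import zone_sum

_PASTURE = "meadow_pasture"


def food_supply(stack: LandscapeStack, t: int, econ: EconTables) -> np.ndarray:
    """Annual food production per municipality (kg).

    Crops: yield (kg/ha) x cropped area per crop class. Livestock: animals
    are stocked on pasture at the class density (animals/ha) and contribute
    their average available meat (kg/animal).
    """
    lc = stack.land_cover[t]
    n = stack.n_zones
    ha_per_pixel = stack.pixel_area / 10_000.0
    supply = np.zeros(n)
    for crop_class, yield_kg_ha in econ.crop_yield.items():
        if crop_class not in LC_CODE:
            raise ConfigurationError(f"unknown crop class {crop_class!r}")
        area_ha = ha_per_pixel * zone_sum(
            (lc == LC_CODE[crop_class]).astype(float), stack.zones, n
        )
        supply += yield_kg_ha * area_ha
    pasture_ha = ha_per_pixel * zone_sum(
        (lc == LC_CODE[_PASTURE]).astype(float), stack.zones, n
    )
    for animal, density in econ.livestock_density.items():
        meat = econ.meat_per_animal.get(animal)
        if meat is None:
            raise ConfigurationError(f"no meat_per_animal entry for {animal!r}")
        supply += meat * density * pasture_ha
    if (supply < 0).any():
        raise InputError("negative food supply implies negative areas or rates")
    return supply


def food_demand(stack: LandscapeStack, t: int, econ: EconTables) -> np.ndarray:
    """Annual food consumption per municipality (kg): per-capita rate x population."""
    population = zone_sum(stack.population[t], stack.zones, stack.n_zones)
    return econ.per_capita_food_demand * population
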