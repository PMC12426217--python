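"""Climate regulation (CLI): NPP carbon-sequestration supply, emission demand.

Net primary productivity (tC/ha/yr by land-cover class) proxies carbon
sequestration; demand converts per-capita CO2-equivalent emissions to carbon
by the molar-mass ratio 12/44. Satellite NPP is unavailable before the
2000s, so earlier timesteps can be back-filled by per-municipality linear
regression over the observed ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import LAND_COVER_CLASSES, ConfigurationError, EconTables, InputError, LandscapeStack
from ..zonal import zone_sum

CO2_TO_C = 12.0 / 44.0  # molar masses: C = 12, O = 16


def climate_supply(stack: LandscapeStack, t: int, econ: EconTables) -> np.ndarray:
    """Annual NPP per municipality (tC): class rate x class area summed."""
    missing = [c for c in LAND_COVER_CLASSES if c not in econ.npp_by_class]
    if missing:
        raise ConfigurationError(f"npp_by_class missing classes {missing}")
    lut = np.array([econ.npp_by_class[c] for c in LAND_COVER_CLASSES])
    npp_per_pixel = lut[stack.land_cover[t]] * (stack.pixel_area / 10_000.0)
    return zone_sum(npp_per_pixel, stack.zones, stack.n_zones)


def climate_demand(stack: LandscapeStack, t: int, econ: EconTables) -> np.ndarray:
    """Annual carbon emissions per municipality (tC)."""
    if t >= len(econ.per_capita_co2e):
        raise ConfigurationError(
            f"per_capita_co2e has no rate for timestep {t}"
        )
    population = zone_sum(stack.population[t], stack.zones, stack.n_zones)
    return econ.per_capita_co2e[t] * population * CO2_TO_C


def npp_backcast(series: pd.DataFrame) -> pd.DataFrame:
    """Fill missing NPP values by per-row OLS over the timestep index.

    ``series`` is municipalities x timesteps (columns in time order) with
    NaN where unobserved. Observed values are kept; missing ones are filled
    from the fitted line and clipped at 0. Every row needs >= 2 observations.
    """
    values = series.to_numpy(dtype=float)
    t_index = np.arange(values.shape[1], dtype=float)
    filled = values.copy()
    for i, row in enumerate(values):
        observed = np.isfinite(row)
        if observed.sum() < 2:
            raise InputError(
                f"row {series.index[i]!r}: need >= 2 observed NPP timesteps, "
                f"got {int(observed.sum())}"
            )
        slope, intercept = np.polyfit(t_index[observed], row[observed], 1)
        predicted = np.clip(intercept + slope * t_index, 0.0, None)
        filled[i, ~observed] = predicted[~observed]
    return pd.DataFrame(filled, index=series.index, columns=series.columns)
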