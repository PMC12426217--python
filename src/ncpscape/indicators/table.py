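"""Assemble the tidy NCP table (municipality x NCP x timestep)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..types import (
    NCP_CODES,
    NCP_UNITS,
    EconTables,
    KernelParams,
    LandscapeStack,
)
from .climate import climate_demand, climate_supply, npp_backcast
from .food import food_demand, food_supply
from .habitat import habitat_demand, habitat_supply, run_degradation_max
from .pollination import PollinationLookups, pollination_demand, pollination_supply
from .recreation import RecreationConfig, recreation_demand, recreation_supply
from .water import WaterConfig, water_demand, water_supply


@dataclass(frozen=True)
class IndicatorParams:
    """All tunable indicator parameters in one place."""

    kernel: KernelParams = field(default_factory=KernelParams)
    pollination: PollinationLookups = field(default_factory=PollinationLookups)
    recreation: RecreationConfig = field(default_factory=RecreationConfig)
    water: WaterConfig = field(default_factory=WaterConfig)
    protection_values: dict[int, float] | None = None
    #: first timestep index with observed NPP; earlier ones are back-filled
    #: by linear regression (None = all observed, no backcast).
    npp_observed_from: int | None = 2


def build_ncp_table(
    stack: LandscapeStack,
    econ: EconTables,
    params: IndicatorParams | None = None,
    ncps: tuple[str, ...] = NCP_CODES,
) -> pd.DataFrame:
    """Compute raw supply and demand for every municipality, NCP and timestep.

    Returns a tidy frame with columns municipality_id, ncp, timestep, supply,
    demand, unit, per_capita (flag, set later by the per-capita transform).
    """
    params = params or IndicatorParams()
    n_t = stack.n_timesteps
    n_zones = stack.n_zones
    labels = list(stack.timestep_labels)

    supply = {ncp: np.empty((n_t, n_zones)) for ncp in ncps}
    demand = {ncp: np.empty((n_t, n_zones)) for ncp in ncps}

    hab_max = (
        run_degradation_max(stack, params.kernel) if "HAB" in ncps else None
    )
    for t in range(n_t):
        if "POL" in ncps:
            supply["POL"][t] = pollination_supply(
                stack, t, params.kernel, params.pollination
            )
            demand["POL"][t] = pollination_demand(stack, t, econ)
        if "HAB" in ncps:
            supply["HAB"][t] = habitat_supply(stack, t, params.protection_values)
            demand["HAB"][t] = habitat_demand(
                stack, t, params.kernel, rescale_max=hab_max
            )
        if "REC" in ncps:
            supply["REC"][t] = recreation_supply(
                stack, t, params.recreation, econ.recreation_value_by_class
            )
            demand["REC"][t] = recreation_demand(
                stack, t, params.recreation, econ.per_capita_recreation_need
            )
        if "FOD" in ncps:
            supply["FOD"][t] = food_supply(stack, t, econ)
            demand["FOD"][t] = food_demand(stack, t, econ)
        if "WAT" in ncps:
            supply["WAT"][t] = water_supply(stack, t, params.water)
            demand["WAT"][t] = water_demand(stack, t, econ)
        if "CLI" in ncps:
            supply["CLI"][t] = climate_supply(stack, t, econ)
            demand["CLI"][t] = climate_demand(stack, t, econ)

    if "CLI" in ncps and params.npp_observed_from:
        first_obs = params.npp_observed_from
        if n_t - first_obs >= 2:  # backcast needs >= 2 observed timesteps
            obs = pd.DataFrame(
                supply["CLI"].T, columns=labels, index=np.arange(n_zones)
            )
            obs.iloc[:, :first_obs] = np.nan
            supply["CLI"] = npp_backcast(obs).to_numpy().T

    rows = []
    for ncp in ncps:
        for t, label in enumerate(labels):
            rows.append(
                pd.DataFrame(
                    {
                        "municipality_id": np.arange(n_zones),
                        "ncp": ncp,
                        "timestep": label,
                        "supply": supply[ncp][t],
                        "demand": demand[ncp][t],
                        "unit": NCP_UNITS[ncp],
                        "per_capita": False,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    table["timestep"] = pd.Categorical(table["timestep"], categories=labels, ordered=True)
    return table
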