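"""Budget and ratio indices from raw supply and demand.

The budget is the difference of jointly min-max-normalized supply and demand
(per NCP, pooled over municipalities and timesteps, shared min/max for both
variables), which bounds it in [-1, 1]. The ratio compares raw same-unit
values, shifted so that 0 means demand exactly met and -1 means no supply:
ratio = supply/demand - 1, bounded below by -1. Food, water and climate are
expressed per capita before either index is formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PER_CAPITA_NCPS, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexConfig:
    #: ratio assigned when demand = 0 with supply > 0 (flagged in the output)
    ratio_cap: float = 99.0
    #: subtract 1 from supply/demand so 0 marks exact balance (the printed
    #: index range [-1, inf) requires the shift); False gives plain s/d
    shifted_ratio: bool = True
    per_capita_ncps: frozenset[str] = PER_CAPITA_NCPS


def per_capita_transform(
    table: pd.DataFrame, population: pd.DataFrame, config: IndexConfig | None = None
) -> pd.DataFrame:
    """Divide FOD/WAT/CLI supply and demand by municipal population.

    ``population`` is municipalities x timesteps (columns = timestep labels).
    Zero population with nonzero supply or demand is an error (the per-capita
    value is undefined). Other NCPs pass through untouched.
    """
    config = config or IndexConfig()
    out = table.copy()
    mask = out["ncp"].isin(config.per_capita_ncps)
    if not mask.any():
        return out
    pop = population.stack()
    keys = pd.MultiIndex.from_frame(
        out.loc[mask, ["municipality_id", "timestep"]].astype(
            {"timestep": str}
        )
    )
    pop_values = pop.reindex(keys).to_numpy(dtype=float)
    if np.isnan(pop_values).any():
        raise InputError("population table missing municipality x timestep entries")
    zero = pop_values <= 0
    touched = (
        out.loc[mask, ["supply", "demand"]].to_numpy()[zero] != 0
    ).any()
    if zero.any() and touched:
        raise InputError(
            "zero population with nonzero supply/demand: per-capita value undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out.loc[mask, "supply"] = out.loc[mask, "supply"].to_numpy() / pop_values
        out.loc[mask, "demand"] = out.loc[mask, "demand"].to_numpy() / pop_values
    out.loc[mask & out["supply"].isna(), "supply"] = 0.0
    out.loc[mask & out["demand"].isna(), "demand"] = 0.0
    out.loc[mask, "per_capita"] = True
    out.loc[mask, "unit"] = out.loc[mask, "unit"] + "/person"
    return out


def joint_minmax(table: pd.DataFrame) -> pd.DataFrame:
    """Per-NCP min/max pooled over supply and demand, municipalities, timesteps."""
    stats = []
    for ncp, group in table.groupby("ncp", observed=True):
        pooled = np.concatenate(
            [group["supply"].to_numpy(float), group["demand"].to_numpy(float)]
        )
        stats.append({"ncp": ncp, "min": pooled.min(), "max": pooled.max()})
    return pd.DataFrame(stats).set_index("ncp")


def normalize(
    table: pd.DataFrame, stats: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max normalize supply and demand on a shared per-NCP scale.

    Sharing one (min, max) between supply and demand keeps their difference
    in [-1, 1]; pooling over timesteps preserves temporal trends. Returns the
    table with supply_norm/demand_norm columns plus the stats used (exported
    as a sidecar for reproducibility). A degenerate NCP (max = min) maps to 0
    with a logged warning.
    """
    if table.empty:
        raise InputError("cannot normalize an empty NCP table")
    if stats is None:
        stats = joint_minmax(table)
    out = table.copy()
    mn = stats["min"].reindex(out["ncp"]).to_numpy(float)
    mx = stats["max"].reindex(out["ncp"]).to_numpy(float)
    span = mx - mn
    degenerate = span <= 0
    if degenerate.any():
        for ncp in sorted(out.loc[degenerate, "ncp"].unique()):
            logger.warning("NCP %s has constant supply/demand; normalized to 0", ncp)
    safe_span = np.where(degenerate, 1.0, span)
    out["supply_norm"] = np.where(
        degenerate, 0.0, (out["supply"].to_numpy(float) - mn) / safe_span
    )
    out["demand_norm"] = np.where(
        degenerate, 0.0, (out["demand"].to_numpy(float) - mn) / safe_span
    )
    return out, stats


def budget(supply_norm: np.ndarray, demand_norm: np.ndarray) -> np.ndarray:
    """Normalized supply minus normalized demand; in [-1, 1] by construction."""
    return np.asarray(supply_norm, float) - np.asarray(demand_norm, float)


def ratio(
    raw_supply: np.ndarray,
    raw_demand: np.ndarray,
    config: IndexConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Demand-met ratio on raw same-unit values; lower bound -1.

    Returns (ratio, capped flag). supply = demand gives 0; supply = 0 with
    demand > 0 gives -1; demand = 0 with supply > 0 is undefined and set to
    the configured cap (flagged); 0/0 gives 0.
    """
    config = config or IndexConfig()
    s = np.asarray(raw_supply, dtype=float)
    d = np.asarray(raw_demand, dtype=float)
    if (s < 0).any() or (d < 0).any():
        raise InputError("ratio requires non-negative supply and demand")
    shift = 1.0 if config.shifted_ratio else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s / d - shift
    capped = (d == 0) & (s > 0)
    r[capped] = config.ratio_cap
    r[(d == 0) & (s == 0)] = 0.0
    return r, capped


def build_index_table(
    table: pd.DataFrame,
    population: pd.DataFrame,
    config: IndexConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw NCP table -> index table (normalized values, budget, ratio).

    Applies the per-capita transform, then joint min-max normalization, then
    both indices. Returns (index table, normalization stats sidecar).
    """
    config = config or IndexConfig()
    out = per_capita_transform(table, population, config)
    out, stats = normalize(out)
    out["budget"] = budget(out["supply_norm"], out["demand_norm"])
    r, capped = ratio(out["supply"].to_numpy(), out["demand"].to_numpy(), config)
    out["ratio"] = r
    out["ratio_capped"] = capped
    return out, stats
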