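"""Temporal trend descriptors per municipality and NCP.

Three variables feed the clustering stage: the current budget (last
timestep), the budget coefficient B_coeff and the ratio coefficient R_coeff
— OLS slopes of the budget and ratio series over the ordinal timestep index.
Slopes are used purely descriptively (no p-values on 4-point fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import InputError


@dataclass(frozen=True)
class TrendConfig:
    #: regressor values per timestep; None = ordinal index 0, 1, 2, ...
    #: (calendar mid-years can be supplied instead)
    regressor: tuple[float, ...] | None = None
    #: deadband for calling a coefficient "neutral" in quadrant labels
    epsilon: float = 1e-6


def slope(series: np.ndarray, regressor: np.ndarray | None = None) -> float:
    """OLS slope of a series against the (ordinal) timestep index.

    Invariant to adding a constant to the series or shifting the regressor.
    Non-finite values are an error: slopes over gap-ridden series would be
    silently biased.
    """
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise InputError("slope needs at least 2 values")
    if not np.isfinite(y).all():
        raise InputError("slope input contains non-finite values")
    x = np.arange(y.size, dtype=float) if regressor is None else np.asarray(regressor, float)
    if x.size != y.size:
        raise InputError("regressor length does not match series length")
    xc = x - x.mean()
    return float((xc * (y - y.mean())).sum() / (xc * xc).sum())


def build_trend_table(
    index_table: pd.DataFrame, config: TrendConfig | None = None
) -> pd.DataFrame:
    """One row per municipality x NCP: current_budget, b_coeff, r_coeff.

    Requires a complete municipality x NCP x timestep grid; any gap is
    reported by name.
    """
    config = config or TrendConfig()
    timesteps = list(index_table["timestep"].cat.categories) if isinstance(
        index_table["timestep"].dtype, pd.CategoricalDtype
    ) else sorted(index_table["timestep"].unique())
    regressor = (
        np.asarray(config.regressor, float) if config.regressor is not None else None
    )
    records = []
    grouped = index_table.groupby(["municipality_id", "ncp"], observed=True)
    for (muni, ncp), group in grouped:
        present = set(map(str, group["timestep"]))
        missing = [t for t in map(str, timesteps) if t not in present]
        if missing:
            raise InputError(
                f"municipality {muni}, NCP {ncp}: missing timesteps {missing}"
            )
        ordered = group.sort_values("timestep")
        budgets = ordered["budget"].to_numpy(float)
        ratios = ordered["ratio"].to_numpy(float)
        records.append(
            {
                "municipality_id": muni,
                "ncp": ncp,
                "current_budget": budgets[-1],
                "b_coeff": slope(budgets, regressor),
                "r_coeff": slope(ratios, regressor),
            }
        )
    return pd.DataFrame.from_records(records)


def classify_quadrant(
    b_coeff: float, r_coeff: float, epsilon: float = 1e-6
) -> str:
    """Stability label from the two coefficient signs.

    Matching signs beyond the deadband mean a stable development
    (improving or declining); a sign mismatch — including one coefficient
    neutral — marks a less stable, mixed trend.
    """
    sb = 0 if abs(b_coeff) <= epsilon else (1 if b_coeff > 0 else -1)
    sr = 0 if abs(r_coeff) <= epsilon else (1 if r_coeff > 0 else -1)
    if sb == sr == 1:
        return "stable_improving"
    if sb == sr == -1:
        return "stable_declining"
    if sb == sr == 0:
        return "neutral"
    return "mixed"


def add_quadrant_labels(
    trend_table: pd.DataFrame, epsilon: float = 1e-6
) -> pd.DataFrame:
    """Trend table with a ``stability`` label column appended."""
    out = trend_table.copy()
    out["stability"] = [
        classify_quadrant(b, r, epsilon)
        for b, r in zip(out["b_coeff"], out["r_coeff"])
    ]
    return out


def cube_root_axes(values: np.ndarray) -> np.ndarray:
    """Sign-preserving cube root, for plot-data export only: sign(x)|x|^(1/3)."""
    v = np.asarray(values, dtype=float)
    return np.sign(v) * np.abs(v) ** (1.0 / 3.0)


def bubble_plot_data(trend_table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready data per NCP: cube-rooted coefficients plus budget size/sign."""
    out = trend_table[["municipality_id", "ncp"]].copy()
    out["r_coeff_cbrt"] = cube_root_axes(trend_table["r_coeff"].to_numpy())
    out["b_coeff_cbrt"] = cube_root_axes(trend_table["b_coeff"].to_numpy())
    out["budget_magnitude"] = trend_table["current_budget"].abs()
    out["budget_sign"] = np.sign(trend_table["current_budget"]).astype(int)
    return out
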