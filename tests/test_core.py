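"""Index semantics: per-capita transform, joint normalization, budget, ratio."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ncpscape import PipelineConfig, run_pipeline
from ncpscape.core import (
    IndexConfig,
    budget,
    normalize,
    per_capita_transform,
    ratio,
)
from ncpscape.types import InputError


def _table(rows):
    df = pd.DataFrame(
        rows,
        columns=["municipality_id", "ncp", "timestep", "supply", "demand"],
    )
    df["unit"] = "u"
    df["per_capita"] = False
    return df


def _population(values):
    return pd.DataFrame(values, columns=["t0"]).rename_axis("municipality_id")


def test_per_capita_transform_divides_food_by_population():
    table = _table([[0, "FOD", "t0", 700_000.0, 350_000.0]])
    out = per_capita_transform(table, _population([1000.0]))
    assert out.loc[0, "supply"] == pytest.approx(700.0)
    assert out.loc[0, "demand"] == pytest.approx(350.0)
    assert bool(out.loc[0, "per_capita"])
    # inverse identity: per-capita value x population recovers the raw total
    assert out.loc[0, "supply"] * 1000.0 == pytest.approx(700_000.0)


def test_per_capita_transform_leaves_pollination_untouched():
    table = _table([[0, "POL", "t0", 0.7, 0.2]])
    out = per_capita_transform(table, _population([1000.0]))
    assert out.loc[0, "supply"] == 0.7
    assert not bool(out.loc[0, "per_capita"])


def test_per_capita_zero_population_with_demand_is_an_error():
    table = _table([[0, "WAT", "t0", 10.0, 5.0]])
    with pytest.raises(InputError):
        per_capita_transform(table, _population([0.0]))


def test_normalize_minmax_definition():
    table = _table(
        [
            [0, "FOD", "t0", 0.0, 5.0],
            [1, "FOD", "t0", 10.0, 5.0],
        ]
    )
    out, stats = normalize(table)
    np.testing.assert_allclose(out["supply_norm"], [0.0, 1.0])
    np.testing.assert_allclose(out["demand_norm"], [0.5, 0.5])
    assert stats.loc["FOD", "min"] == 0.0 and stats.loc["FOD", "max"] == 10.0


def test_normalize_shares_scale_between_supply_and_demand():
    """Supply max 10, demand max 8: demand 8 maps to 0.8, not 1.0."""
    table = _table(
        [
            [0, "WAT", "t0", 10.0, 8.0],
            [1, "WAT", "t0", 0.0, 0.0],
        ]
    )
    out, _ = normalize(table)
    assert out.loc[0, "demand_norm"] == pytest.approx(0.8)
    assert out.loc[0, "supply_norm"] == pytest.approx(1.0)


def test_normalize_is_idempotent_on_unit_interval_indices():
    table = _table(
        [
            [0, "POL", "t0", 0.0, 0.3],
            [1, "POL", "t0", 1.0, 0.6],
        ]
    )
    out, _ = normalize(table)
    np.testing.assert_allclose(out["supply_norm"], out["supply"])
    np.testing.assert_allclose(out["demand_norm"], out["demand"])


def test_normalize_degenerate_ncp_warns_and_zeroes(caplog):
    table = _table([[0, "CLI", "t0", 3.0, 3.0], [1, "CLI", "t0", 3.0, 3.0]])
    with caplog.at_level("WARNING"):
        out, _ = normalize(table)
    assert (out["supply_norm"] == 0).all() and (out["demand_norm"] == 0).all()
    assert any("CLI" in r.message for r in caplog.records)


def test_budget_is_difference_with_printed_bounds():
    assert budget(0.8, 0.3) == pytest.approx(0.5)
    assert budget(0.42, 0.42) == 0.0
    assert budget(0.0, 1.0) == -1.0  # printed lower bound of the index


@pytest.mark.parametrize(
    "supply, demand, expected",
    [(100.0, 100.0, 0.0), (0.0, 50.0, -1.0), (150.0, 100.0, 0.5), (0.0, 0.0, 0.0)],
)
def test_ratio_shifted_semantics(supply, demand, expected):
    r, capped = ratio(np.array([supply]), np.array([demand]))
    assert r[0] == pytest.approx(expected)
    assert not capped[0]


def test_ratio_caps_undefined_division_and_flags_it():
    r, capped = ratio(np.array([5.0]), np.array([0.0]))
    assert r[0] == 99.0 and capped[0]
    r2, _ = ratio(np.array([5.0]), np.array([0.0]), IndexConfig(ratio_cap=10.0))
    assert r2[0] == 10.0


def test_ratio_rejects_negative_inputs():
    with pytest.raises(InputError):
        ratio(np.array([-1.0]), np.array([1.0]))


def test_unshifted_ratio_variant():
    r, _ = ratio(np.array([150.0]), np.array([100.0]), IndexConfig(shifted_ratio=False))
    assert r[0] == pytest.approx(1.5)


def test_budget_and_ratio_decrease_with_demand():
    demands = np.array([1.0, 2.0, 5.0, 10.0])
    supply = np.full_like(demands, 4.0)
    r, _ = ratio(supply, demands)
    assert (np.diff(r) < 0).all()
    # budgets on a shared scale: fixed supply_norm, growing demand_norm
    b = budget(0.4, demands / demands.max())
    assert (np.diff(b) < 0).all()


def test_sign_coherence_on_generated_region():
    """budget > 0 iff ratio > 0 wherever demand > 0 (shared-scale normalization
    is order-preserving, so both indices compare the same raw quantities)."""
    cfg = PipelineConfig(
        region={"n_municipalities": 16, "grid_shape": [48, 48],
                "population_total": 12_000.0, "seed": 21},
        output_dir=None,
    )
    res = run_pipeline(cfg)
    idx = res.index_table
    rows = idx[(idx["demand"] > 0) & ~idx["ratio_capped"]]
    tol = 1e-9
    decided = rows[(rows["budget"].abs() > tol) & (rows["ratio"].abs() > tol)]
    assert len(decided) > 100
    assert (np.sign(decided["budget"]) == np.sign(decided["ratio"])).all()
    # range guarantees on real pipeline output
    assert idx["budget"].between(-1.0, 1.0).all()
    assert (idx["ratio"] >= -1.0 - 1e-12).all()
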