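"""Arithmetic oracles and limit behavior for the six indicator models."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
import sympy

from ncpscape.indicators import (
    RecreationConfig,
    budyko_fu_yield,
    climate_demand,
    climate_supply,
    food_demand,
    food_supply,
    habitat_demand,
    habitat_supply,
    npp_backcast,
    pollination_demand,
    recreation_demand,
    recreation_supply,
    water_demand,
    water_supply,
)
from ncpscape.types import LC_CODE, ConfigurationError, InputError

from conftest import make_stack


# ------------------------------------------------------------- pollination

def test_pollination_demand_cases(econ):
    h = w = 10
    forest = make_stack(np.full((h, w), LC_CODE["forest"]))
    assert pollination_demand(forest, 0, econ)[0] == 0.0

    hort = make_stack(np.full((h, w), LC_CODE["horticulture"]))
    assert pollination_demand(hort, 0, econ)[0] == pytest.approx(1.0)

    half = np.full((h, w), LC_CODE["cropland"])
    half[:, : w // 2] = LC_CODE["horticulture"]
    mixed = make_stack(half)
    econ2 = dataclasses.replace(
        econ, crop_pollinator_dependence={"horticulture": 0.65, "cropland": 0.05}
    )
    expected = (0.5 * 0.65 + 0.5 * 0.05) / 0.65
    assert pollination_demand(mixed, 0, econ2)[0] == pytest.approx(expected)


# ----------------------------------------------------------------- habitat

def test_habitat_supply_protection_levels():
    lc = np.full((8, 8), LC_CODE["forest"])
    none = make_stack(lc)
    assert habitat_supply(none)[0] == 0.0

    full = make_stack(lc, protection=np.full((8, 8), 4, dtype=np.int8))
    assert habitat_supply(full)[0] == 1.0

    half = np.zeros((8, 8), dtype=np.int8)
    half[:4] = 2
    assert habitat_supply(make_stack(lc, protection=half))[0] == pytest.approx(0.25)

    with pytest.raises(ConfigurationError):
        habitat_supply(make_stack(lc, protection=np.full((8, 8), 7, dtype=np.int8)))


def test_habitat_demand_zero_threats_and_insensitive_class():
    lc = np.full((10, 10), LC_CODE["settlement"])  # sensitivity 0 to urban threat
    stack = make_stack(lc, threats={"urban": np.zeros((10, 10))})
    np.testing.assert_array_equal(habitat_demand(stack, 0), 0.0)

    stack2 = make_stack(lc, threats={"urban": np.ones((10, 10))})
    np.testing.assert_array_equal(habitat_demand(stack2, 0), 0.0)


# -------------------------------------------------------------- recreation

def test_recreation_supply_threshold_and_area():
    lc = np.full((5, 5), LC_CODE["settlement"])  # value 0.1, below threshold
    stack = make_stack(lc)
    assert recreation_supply(stack, 0)[0] == 0.0

    # single-pixel municipality: a park next to water reaches v = 1.0
    lc2 = np.full((5, 5), LC_CODE["settlement"])
    lc2[2, 2] = LC_CODE["park_public"]
    lc2[2, 3] = LC_CODE["water"]
    zones = np.ones((5, 5), dtype=np.int32)
    zones[2, 2] = 0
    stack2 = make_stack(lc2, zones=zones)
    result = recreation_supply(stack2, 0)
    assert result[0] == pytest.approx(1.0 * 10_000.0 * 0.5)  # v x area x usable

    # raising the threshold never increases supply
    low = recreation_supply(stack2, 0, RecreationConfig(threshold=0.3))
    high = recreation_supply(stack2, 0, RecreationConfig(threshold=0.8))
    assert (high <= low).all()

    with pytest.raises(ConfigurationError):
        RecreationConfig(threshold=1.5)


def test_recreation_demand_uniform_population():
    lc = np.full((9, 9), LC_CODE["forest"])
    stack = make_stack(lc, population=np.full((9, 9), 2.5))
    result = recreation_demand(stack, 0, per_capita_need=30.0)
    np.testing.assert_allclose(result, 2.5 * 30.0, rtol=1e-12)

    empty = make_stack(lc)
    np.testing.assert_array_equal(recreation_demand(empty, 0), 0.0)


def test_recreation_demand_single_person_matches_enumeration():
    lc = np.full((3, 3), LC_CODE["forest"])
    pop = np.zeros((3, 3))
    pop[1, 1] = 1.0
    stack = make_stack(lc, population=pop)
    config = RecreationConfig(walk_radius=100.0)  # one pixel
    demand = recreation_demand(stack, 0, config, per_capita_need=30.0)
    # brute force: population within Euclidean radius / pixels within radius
    h = w = 3
    expected_field = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            total = count = 0.0
            for y in range(h):
                for x in range(w):
                    if np.hypot(i - y, j - x) * 100.0 <= 100.0:
                        total += pop[y, x]
                        count += 1
            expected_field[i, j] = total / count * 30.0
    np.testing.assert_allclose(demand[0], expected_field.mean(), rtol=1e-12)


# -------------------------------------------------------------------- food

def test_food_supply_oracles(econ):
    lc = np.full((10, 10), LC_CODE["water"])
    lc[:, :5] = LC_CODE["cropland"]  # 50 pixels = 50 ha... use 100 below
    lc100 = np.full((10, 10), LC_CODE["cropland"])  # 100 pixels of 1 ha
    econ_wheat = dataclasses.replace(
        econ, crop_yield={"cropland": 6000.0}, livestock_density={}, meat_per_animal={}
    )
    assert food_supply(make_stack(lc100), 0, econ_wheat)[0] == pytest.approx(600_000.0)

    half = food_supply(make_stack(lc), 0, econ_wheat)[0]
    assert half * 2 == pytest.approx(600_000.0)  # linear in cropped area

    barren = make_stack(np.full((10, 10), LC_CODE["water"]))
    assert food_supply(barren, 0, econ)[0] == 0.0


def test_food_demand_oracle_and_additivity(econ):
    lc = np.full((10, 10), LC_CODE["settlement"])
    pop = np.full((10, 10), 10.0)  # 1000 persons
    stack = make_stack(lc, population=pop)
    assert food_demand(stack, 0, econ)[0] == pytest.approx(1000.0 * 700.0)

    zones = np.zeros((10, 10), dtype=np.int32)
    zones[5:] = 1
    split = make_stack(lc, zones=zones, population=pop)
    per_zone = food_demand(split, 0, econ)
    assert per_zone.sum() == pytest.approx(1000.0 * 700.0)

    empty = make_stack(lc)
    assert food_demand(empty, 0, econ)[0] == 0.0


# ------------------------------------------------------------------- water

def test_budyko_limits():
    p = np.array([1000.0])
    assert budyko_fu_yield(p, np.array([0.0]), 2.6)[0] == pytest.approx(1000.0)
    assert budyko_fu_yield(p, np.array([1e9]), 2.6)[0] == pytest.approx(0.0, abs=1e-6)


def test_budyko_against_symbolic_evaluation():
    """Fu's curve at P=1000, PET=800, omega=2.6 vs 50-digit sympy arithmetic."""
    p_val, pet_val, om = 1000.0, 800.0, 2.6
    phi = sympy.Rational(8, 10)
    omega = sympy.Rational(26, 10)
    aet_over_p = 1 + phi - (1 + phi**omega) ** (1 / omega)
    expected = float((1 - aet_over_p) * 1000)
    got = budyko_fu_yield(np.array([p_val]), np.array([pet_val]), om)[0]
    assert got == pytest.approx(expected, rel=1e-10)


def test_water_supply_unit_conversion():
    lc = np.full((10, 10), LC_CODE["settlement"])
    stack = make_stack(lc, precipitation=1000.0, pet=0.0)
    # PET=0 -> yield = P; 100 pixels x 10,000 m2 x 1000 mm -> 1e6 m3
    assert water_supply(stack, 0)[0] == pytest.approx(1_000_000.0)


def test_water_demand_oracle(econ):
    lc = np.full((10, 10), LC_CODE["forest"])
    lc[:5] = LC_CODE["cropland"]  # 50 cropland pixels
    pop = np.full((10, 10), 10.0)  # 1000 persons
    stack = make_stack(lc, population=pop)
    econ2 = dataclasses.replace(
        econ,
        per_capita_water_demand=100.0,
        sectoral_water_demand={"cropland": 20.0},
    )
    assert water_demand(stack, 0, econ2)[0] == pytest.approx(
        1000.0 * 100.0 + 50 * 20.0
    )
    # household term is linear in population
    stack2 = make_stack(lc, population=2 * pop)
    d2 = water_demand(stack2, 0, econ2)[0]
    assert d2 == pytest.approx(2000.0 * 100.0 + 50 * 20.0)


# ------------------------------------------------------------------ climate

def test_climate_supply_oracle(econ):
    lc = np.full((10, 20), LC_CODE["forest"])  # 200 ha
    stack = make_stack(lc)
    econ2 = dataclasses.replace(econ, npp_by_class={**econ.npp_by_class, "forest": 6.0})
    assert climate_supply(stack, 0, econ2)[0] == pytest.approx(1200.0)

    zero = dataclasses.replace(
        econ, npp_by_class={c: 0.0 for c in econ.npp_by_class}
    )
    assert climate_supply(stack, 0, zero)[0] == 0.0


def test_climate_demand_molar_ratio(econ):
    lc = np.full((5, 5), LC_CODE["settlement"])
    pop = np.full((5, 5), 4.0)  # 100 persons
    stack = make_stack(lc, population=pop)
    econ2 = dataclasses.replace(econ, per_capita_co2e=(0.44, 0.44, 0.44, 0.44))
    # 100 x 0.44 = 44 tCO2e -> 12 tC
    assert climate_demand(stack, 0, econ2)[0] == pytest.approx(12.0)
    assert climate_demand(make_stack(lc), 0, econ2)[0] == 0.0
    double = dataclasses.replace(econ, per_capita_co2e=(0.88, 0.88, 0.88, 0.88))
    assert climate_demand(stack, 0, double)[0] == pytest.approx(24.0)


def test_npp_backcast_two_point_line():
    series = pd.DataFrame(
        [[np.nan, np.nan, 100.0, 110.0]], columns=["a", "b", "c", "d"]
    )
    filled = npp_backcast(series)
    np.testing.assert_allclose(filled.iloc[0], [80.0, 90.0, 100.0, 110.0])


def test_npp_backcast_constant_and_clipping():
    const = pd.DataFrame([[np.nan, 50.0, 50.0, 50.0]])
    np.testing.assert_allclose(npp_backcast(const).iloc[0], 50.0)

    steep = pd.DataFrame([[np.nan, np.nan, 10.0, 200.0]])
    assert npp_backcast(steep).iloc[0, 0] == 0.0  # would be negative

    with pytest.raises(InputError):
        npp_backcast(pd.DataFrame([[np.nan, np.nan, np.nan, 5.0]]))
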