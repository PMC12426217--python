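"""Shared fixtures: small synthetic regions and hand-built toy landscapes."""

from __future__ import annotations

import numpy as np
import pytest

from ncpscape.synth import default_econ_tables, generate_region
from ncpscape.types import LC_CODE, LandscapeStack, RegionSpec


@pytest.fixture(scope="session")
def small_spec() -> RegionSpec:
    """Desk-sized region: 60x60 grid, 24 municipalities, 4 archetypes."""
    return RegionSpec(
        n_municipalities=24,
        grid_shape=(60, 60),
        population_total=25_000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_region(small_spec):
    return generate_region(small_spec)


@pytest.fixture(scope="session")
def small_stack(small_region) -> LandscapeStack:
    return small_region[0]


@pytest.fixture(scope="session")
def econ():
    return default_econ_tables()


def make_stack(
    land_cover: np.ndarray,
    zones: np.ndarray | None = None,
    population: np.ndarray | None = None,
    protection: np.ndarray | None = None,
    precipitation: float | np.ndarray = 1000.0,
    pet: float | np.ndarray = 600.0,
    threats: dict[str, np.ndarray] | None = None,
    pixel_area: float = 10_000.0,
    n_timesteps: int | None = None,
) -> LandscapeStack:
    """Hand-built landscape: single class raster repeated over timesteps."""
    land_cover = np.asarray(land_cover, dtype=np.int8)
    if land_cover.ndim == 2:
        n_t = n_timesteps or 4
        land_cover = np.repeat(land_cover[None], n_t, axis=0)
    n_t, h, w = land_cover.shape
    labels = tuple(f"t{t}" for t in range(n_t))
    if zones is None:
        zones = np.zeros((h, w), dtype=np.int32)
    if population is None:
        population = np.zeros_like(land_cover, dtype=float)
    elif population.ndim == 2:
        population = np.repeat(population[None].astype(float), n_t, axis=0)
    if protection is None:
        protection = np.zeros((h, w), dtype=np.int8)
    if threats is None:
        threats = {
            "urban": (land_cover == LC_CODE["settlement"]).astype(float),
            "agriculture": 0.8
            * np.isin(
                land_cover, [LC_CODE["cropland"], LC_CODE["horticulture"]]
            ).astype(float),
        }
    else:
        threats = {
            k: (np.repeat(v[None], n_t, axis=0) if np.asarray(v).ndim == 2 else v)
            for k, v in threats.items()
        }
    return LandscapeStack(
        land_cover=land_cover,
        population=population,
        protection=protection,
        threat_layers=threats,
        precipitation=np.broadcast_to(np.asarray(precipitation, float), (h, w)).copy(),
        pet=np.broadcast_to(np.asarray(pet, float), (h, w)).copy(),
        zones=np.asarray(zones, dtype=np.int32),
        pixel_area=pixel_area,
        timestep_labels=labels,
    )
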