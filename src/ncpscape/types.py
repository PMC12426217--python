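"""Domain containers shared across the pipeline.

All rasters are plain numpy arrays on one shared grid in a local metric
(projected) coordinate system with square pixels. Time-varying rasters carry
the timestep axis first, shape ``(T, H, W)``; static rasters are ``(H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Closed set of land-cover classes, in fixed code order (raster values 0..7).
LAND_COVER_CLASSES: tuple[str, ...] = (
    "settlement",
    "cropland",
    "horticulture",
    "forest",
    "meadow_pasture",
    "water",
    "park_public",
    "other",
)

LC_CODE: dict[str, int] = {name: i for i, name in enumerate(LAND_COVER_CLASSES)}

#: The six NCPs assessed, in canonical order.
NCP_CODES: tuple[str, ...] = ("POL", "HAB", "REC", "FOD", "WAT", "CLI")

#: NCPs whose raw supply/demand are expressed per capita before indexing.
PER_CAPITA_NCPS: frozenset[str] = frozenset({"FOD", "WAT", "CLI"})

#: Units of the raw indicator values, per NCP (supply and demand share units).
NCP_UNITS: dict[str, str] = {
    "POL": "index[0,1]",
    "HAB": "index[0,1]",
    "REC": "m2",
    "FOD": "kg",
    "WAT": "m3",
    "CLI": "tC",
}

DEFAULT_TIMESTEP_LABELS: tuple[str, ...] = ("1980s", "1990s", "2000s", "current")


class ConfigurationError(ValueError):
    """A parameter table or lookup is inconsistent with the landscape."""


class InputError(ValueError):
    """Input data violate a precondition (negative areas, missing records...)."""


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic study region.

    The defaults describe a canton-scale miniature: a 200x200 grid of 1-ha
    pixels (400 km2), 60 municipalities, four decadal timesteps and four
    planted socio-ecological archetypes, with regional population growing
    ~60% over the whole period.
    """

    n_municipalities: int = 60
    grid_shape: tuple[int, int] = (200, 200)
    pixel_area: float = 10_000.0  # m2 (1 ha)
    n_timesteps: int = 4
    timestep_labels: tuple[str, ...] = DEFAULT_TIMESTEP_LABELS
    n_archetypes: int = 4
    archetype_mixing: float = 0.1
    noise_sd: float = 0.3
    population_total: float = 150_000.0  # regional total at the first timestep
    population_growth: float = 0.6  # fractional growth over the full period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timesteps < 2:
            raise ConfigurationError("n_timesteps must be >= 2")
        if not (1 <= self.n_archetypes <= self.n_municipalities):
            raise ConfigurationError(
                "n_archetypes must be in [1, n_municipalities]"
            )
        if len(self.timestep_labels) != self.n_timesteps:
            raise ConfigurationError(
                f"{self.n_timesteps} timesteps but "
                f"{len(self.timestep_labels)} labels"
            )
        if not (0.0 <= self.archetype_mixing <= 1.0):
            raise ConfigurationError("archetype_mixing must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_municipalities > self.grid_shape[0] * self.grid_shape[1]:
            raise ConfigurationError("more municipalities than pixels")

    @property
    def pixel_size(self) -> float:
        """Pixel edge length in metres."""
        return float(np.sqrt(self.pixel_area))


@dataclass
class LandscapeStack:
    """Per-timestep raster bundle on one shared grid.

    ``zones`` assigns every pixel to exactly one municipality id in
    ``0..n_zones-1`` (a full partition); ``threat_layers`` maps a threat name
    to a ``(T, H, W)`` intensity raster in [0, 1].
    """

    land_cover: np.ndarray  # (T, H, W) int codes into LAND_COVER_CLASSES
    population: np.ndarray  # (T, H, W) persons per pixel, >= 0
    protection: np.ndarray  # (H, W) int protection level 0..4
    threat_layers: dict[str, np.ndarray]  # name -> (T, H, W) in [0, 1]
    precipitation: np.ndarray  # (H, W) mm/yr
    pet: np.ndarray  # (H, W) mm/yr potential evapotranspiration
    zones: np.ndarray  # (H, W) int municipality id
    pixel_area: float = 10_000.0  # m2
    timestep_labels: tuple[str, ...] = DEFAULT_TIMESTEP_LABELS
    crs: str = "local-metric"

    @property
    def n_timesteps(self) -> int:
        return int(self.land_cover.shape[0])

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.land_cover.shape[1:])  # type: ignore[return-value]

    @property
    def n_zones(self) -> int:
        return int(self.zones.max()) + 1

    @property
    def pixel_size(self) -> float:
        return float(np.sqrt(self.pixel_area))

    def validate(self) -> list[str]:
        """Return a list of consistency issues (empty when valid)."""
        issues: list[str] = []
        h, w = self.grid_shape
        t = self.n_timesteps
        if self.land_cover.shape != (t, h, w):
            issues.append("land_cover shape inconsistent")
        if self.population.shape != (t, h, w):
            issues.append(
                f"population shape {self.population.shape} != {(t, h, w)}"
            )
        for name, layer in self.threat_layers.items():
            if layer.shape != (t, h, w):
                issues.append(f"threat layer {name!r} shape {layer.shape} != {(t, h, w)}")
            elif layer.min() < 0 or layer.max() > 1:
                issues.append(f"threat layer {name!r} outside [0, 1]")
        for name, arr in (
            ("protection", self.protection),
            ("precipitation", self.precipitation),
            ("pet", self.pet),
            ("zones", self.zones),
        ):
            if arr.shape != (h, w):
                issues.append(f"{name} shape {arr.shape} != {(h, w)}")
        if self.population.size and self.population.min() < 0:
            issues.append("negative population")
        if self.land_cover.size:
            codes = np.unique(self.land_cover)
            bad = codes[(codes < 0) | (codes >= len(LAND_COVER_CLASSES))]
            if bad.size:
                issues.append(f"unknown land-cover codes {bad.tolist()}")
        zone_ids = np.unique(self.zones)
        if zone_ids.size and (zone_ids != np.arange(zone_ids.size)).any():
            issues.append("zone ids are not a dense 0..n-1 range")
        return issues


@dataclass
class EconTables:
    """Socio-economic rate tables feeding the demand/supply indicators.

    All rates are non-negative; pollinator-dependence fractions are in [0, 1].
    """

    crop_yield: dict[str, float]  # kg/ha by crop land-cover class
    crop_pollinator_dependence: dict[str, float]  # class -> yield-loss fraction
    livestock_density: dict[str, float]  # animals/ha of pasture by livestock class
    meat_per_animal: dict[str, float]  # kg by livestock class
    per_capita_food_demand: float  # kg/person/yr
    per_capita_water_demand: float  # m3/person/yr
    sectoral_water_demand: dict[str, float]  # m3/pixel/yr by land-cover class
    per_capita_co2e: tuple[float, ...]  # tCO2e/person/yr per timestep
    npp_by_class: dict[str, float]  # tC/ha/yr by land-cover class
    recreation_value_by_class: dict[str, float]  # index [0, 1]
    per_capita_recreation_need: float = 30.0  # m2/person

    def __post_init__(self) -> None:
        for name in (
            "crop_yield",
            "livestock_density",
            "meat_per_animal",
            "sectoral_water_demand",
            "npp_by_class",
        ):
            table: Mapping[str, float] = getattr(self, name)
            if any(v < 0 for v in table.values()):
                raise ConfigurationError(f"{name} has negative rates")
        if any(
            not (0.0 <= v <= 1.0) for v in self.crop_pollinator_dependence.values()
        ):
            raise ConfigurationError(
                "crop_pollinator_dependence fractions must be in [0, 1]"
            )
        if any(not (0.0 <= v <= 1.0) for v in self.recreation_value_by_class.values()):
            raise ConfigurationError("recreation_value_by_class must be in [0, 1]")
        if min(self.per_capita_co2e, default=0.0) < 0:
            raise ConfigurationError("per_capita_co2e has negative rates")


@dataclass(frozen=True)
class KernelParams:
    """Distance-kernel parameters for the pollination and habitat models.

    ``foraging_distance_alpha`` is the e-folding distance of the pollinator
    foraging kernel exp(-d/alpha); the kernel is truncated at
    ``truncation_radius``. Threat decay over distance is linear
    (1 - d/d_max) or exponential (exp(-2.99 d/d_max)), clipped at d_max.
    """

    foraging_distance_alpha: float = 500.0  # m
    truncation_radius: float = 1000.0  # m, default 2*alpha
    threat_decay: Mapping[str, str] = field(
        default_factory=lambda: {"urban": "exponential", "agriculture": "linear"}
    )
    threat_max_distance: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 1000.0, "agriculture": 500.0}
    )
    threat_weight: Mapping[str, float] = field(
        default_factory=lambda: {"urban": 1.0, "agriculture": 0.6}
    )
    # habitat sensitivity per land-cover class per threat, in [0, 1]
    habitat_sensitivity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "urban": {
                "settlement": 0.0,
                "cropland": 0.3,
                "horticulture": 0.3,
                "forest": 0.8,
                "meadow_pasture": 0.7,
                "water": 0.6,
                "park_public": 0.4,
                "other": 0.5,
            },
            "agriculture": {
                "settlement": 0.0,
                "cropland": 0.1,
                "horticulture": 0.1,
                "forest": 0.6,
                "meadow_pasture": 0.5,
                "water": 0.7,
                "park_public": 0.3,
                "other": 0.4,
            },
        }
    )

    def __post_init__(self) -> None:
        if self.foraging_distance_alpha <= 0:
            raise ConfigurationError("foraging_distance_alpha must be > 0")
        if self.truncation_radius < self.foraging_distance_alpha:
            raise ConfigurationError("truncation_radius must be >= alpha")
        for name, mode in self.threat_decay.items():
            if mode not in ("linear", "exponential"):
                raise ConfigurationError(
                    f"threat {name!r}: decay must be linear or exponential"
                )
        if any(not (0 <= w <= 1) for w in self.threat_weight.values()):
            raise ConfigurationError("threat weights must be in [0, 1]")
        for threat, table in self.habitat_sensitivity.items():
            if any(not (0 <= s <= 1) for s in table.values()):
                raise ConfigurationError(
                    f"habitat sensitivities for {threat!r} must be in [0, 1]"
                )
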