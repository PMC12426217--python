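"""Pipeline configuration: YAML in, validated parameter objects out.

Every parameter has a default; a YAML file containing only ``mode:
synthetic`` (or nothing at all) is runnable end to end. The ``show-config``
CLI subcommand prints the fully resolved defaults so no constant stays
hidden in code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import IndexConfig
from .indicators.pollination import PollinationLookups
from .indicators.recreation import RecreationConfig
from .indicators.table import IndicatorParams
from .indicators.water import WaterConfig
from .trends import TrendConfig
from .types import NCP_CODES, ConfigurationError, KernelParams, RegionSpec


@dataclass
class ClusterConfig:
    linkage: str = "ward"
    k: int | None = None  # fixed cluster count; None = select from k_range
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    selection: str = "silhouette"  # or "merge_gap"
    standardize: bool = True
    on_constant: str = "error"  # or "zero"


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "files"
    input_dir: str | None = None  # required in files mode
    region: dict[str, Any] = field(default_factory=dict)  # RegionSpec overrides
    ncps: tuple[str, ...] = NCP_CODES
    indicators: dict[str, Any] = field(default_factory=dict)
    index: dict[str, Any] = field(default_factory=dict)
    trend: dict[str, Any] = field(default_factory=dict)
    clustering: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "ncpscape_out"
    write_rasters: bool = False
    write_geojson: bool = False
    seed: int | None = None  # overrides region.seed when given
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ConfigurationError("files mode requires input_dir")
        unknown = [n for n in self.ncps if n not in NCP_CODES]
        if unknown:
            raise ConfigurationError(f"unknown NCP codes {unknown}")
        self.ncps = tuple(self.ncps)

    # ------------------------------------------------ resolved sub-configs

    def region_spec(self) -> RegionSpec:
        params = dict(self.region)
        if self.seed is not None:
            params["seed"] = self.seed
        if "grid_shape" in params:
            params["grid_shape"] = tuple(params["grid_shape"])
        if "timestep_labels" in params:
            params["timestep_labels"] = tuple(params["timestep_labels"])
        return RegionSpec(**params)

    def indicator_params(self) -> IndicatorParams:
        params = dict(self.indicators)
        kernel = KernelParams(**params.pop("kernel", {}))
        pollination = PollinationLookups(**params.pop("pollination", {}))
        recreation = RecreationConfig(**params.pop("recreation", {}))
        water = WaterConfig(**params.pop("water", {}))
        protection_values = params.pop("protection_values", None)
        if protection_values is not None:
            protection_values = {int(k): float(v) for k, v in protection_values.items()}
        npp_observed_from = params.pop("npp_observed_from", 2)
        if params:
            raise ConfigurationError(f"unknown indicator options {sorted(params)}")
        return IndicatorParams(
            kernel=kernel,
            pollination=pollination,
            recreation=recreation,
            water=water,
            protection_values=protection_values,
            npp_observed_from=npp_observed_from,
        )

    def index_config(self) -> IndexConfig:
        params = dict(self.index)
        if "per_capita_ncps" in params:
            params["per_capita_ncps"] = frozenset(params["per_capita_ncps"])
        return IndexConfig(**params)

    def trend_config(self) -> TrendConfig:
        params = dict(self.trend)
        if params.get("regressor") is not None:
            params["regressor"] = tuple(params["regressor"])
        return TrendConfig(**params)

    def cluster_config(self) -> ClusterConfig:
        params = dict(self.clustering)
        if "k_range" in params:
            params["k_range"] = tuple(params["k_range"])
        return ClusterConfig(**params)

    # --------------------------------------------------------- (de)serialize

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ncps"] = list(self.ncps)
        return d

    def config_hash(self) -> str:
        """Hash of the computational parameters (output location and logging
        are excluded: they do not affect the results)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        canonical = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys {unknown}")
        if "ncps" in data:
            data = {**data, "ncps": tuple(data["ncps"])}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path


def resolved_defaults() -> dict[str, Any]:
    """Every tunable parameter with its effective default, for show-config."""
    cfg = PipelineConfig()
    return {
        "pipeline": cfg.to_dict(),
        "region": dataclasses.asdict(cfg.region_spec()),
        "indicators": dataclasses.asdict(cfg.indicator_params()),
        "index": {
            "ratio_cap": cfg.index_config().ratio_cap,
            "shifted_ratio": cfg.index_config().shifted_ratio,
            "per_capita_ncps": sorted(cfg.index_config().per_capita_ncps),
        },
        "trend": dataclasses.asdict(cfg.trend_config()),
        "clustering": dataclasses.asdict(cfg.cluster_config()),
    }
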