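"""End-to-end orchestration: synth -> indicators -> indices -> trends -> clusters.

Each stage's table is written to the output directory; a manifest records
the config hash, seed and a checksum per artifact so identical configs
produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster import (
    ClusterResult,
    FeatureMatrix,
    assemble_features,
    hierarchical_cluster,
    profile_clusters,
    select_k,
    sign_summary,
)
from .config import PipelineConfig
from .core import build_index_table
from .indicators.table import build_ncp_table
from .synth.region import generate_region
from .trends import add_quadrant_labels, bubble_plot_data, build_trend_table
from .types import EconTables, InputError, LandscapeStack
from .zonal import zone_sum

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class PipelineResult:
    stack: LandscapeStack
    econ: EconTables
    ncp_table: pd.DataFrame
    index_table: pd.DataFrame
    normalization: pd.DataFrame
    trend_table: pd.DataFrame
    features: FeatureMatrix
    clusters: ClusterResult
    manifest: dict
    output_dir: Path | None = None


def municipal_population(stack: LandscapeStack) -> pd.DataFrame:
    """Municipality x timestep population totals."""
    totals = np.stack(
        [
            zone_sum(stack.population[t], stack.zones, stack.n_zones)
            for t in range(stack.n_timesteps)
        ]
    )
    return pd.DataFrame(
        totals.T,
        index=pd.RangeIndex(stack.n_zones, name="municipality_id"),
        columns=list(stack.timestep_labels),
    )


def validate_stack(stack: LandscapeStack) -> list[str]:
    """Machine-readable issue list for a landscape stack (empty = valid)."""
    issues = stack.validate()
    if stack.n_timesteps != len(stack.timestep_labels):
        issues.append("timestep labels do not match raster count")
    return issues


def validate_inputs(directory: str | Path) -> list[str]:
    """Validate an on-disk input bundle (alignment, class codes, timesteps)."""
    try:
        stack = io.read_stack(Path(directory))
    except (InputError, FileNotFoundError, KeyError) as exc:
        return [str(exc)]
    return validate_stack(stack)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute all stages and write the artifact bundle.

    With ``output_dir`` set (the default), the NCP table, index table,
    normalization sidecar, trend table, per-NCP plot data, feature matrix and
    cluster outputs are written as CSV/JSON; rasters and the zone GeoJSON
    are written when the corresponding flags are on.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    if config.mode == "synthetic":
        spec = config.region_spec()
        stack, econ = _stage("synth")(generate_region, spec)
    else:
        stack = _stage("read")(io.read_stack, config.input_dir)
        econ = _stage("read")(
            io.read_econ_tables, Path(config.input_dir) / "econ_tables.csv"
        )
    issues = validate_stack(stack)
    if issues:
        raise PipelineError(f"stage 'validate' failed: {issues}")

    ncp_table = _stage("indicators")(
        build_ncp_table, stack, econ, config.indicator_params(), config.ncps
    )
    population = municipal_population(stack)
    index_table, norm_stats = _stage("indices")(
        build_index_table, ncp_table, population, config.index_config()
    )
    trend_cfg = config.trend_config()
    trend_table = _stage("trends")(build_trend_table, index_table, trend_cfg)
    trend_table = add_quadrant_labels(trend_table, trend_cfg.epsilon)

    cluster_cfg = config.cluster_config()
    features = _stage("cluster")(
        assemble_features, trend_table, cluster_cfg.standardize, cluster_cfg.on_constant
    )
    k = cluster_cfg.k or _stage("cluster")(
        select_k, features, cluster_cfg.k_range, cluster_cfg.selection,
        cluster_cfg.linkage,
    )
    result = _stage("cluster")(
        hierarchical_cluster, features, cluster_cfg.linkage, k
    )
    result = profile_clusters(result, features, stack)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed if config.seed is not None else config.region_spec().seed
        if config.mode == "synthetic" else None,
        "n_municipalities": int(stack.n_zones),
        "n_timesteps": int(stack.n_timesteps),
        "ncps": list(config.ncps),
        "selected_k": int(result.k),
        "artifacts": {},
    }

    output_dir: Path | None = None
    if config.output_dir:
        output_dir = Path(config.output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        artifacts = {
            "ncp_table.csv": lambda p: io.write_table(p, ncp_table),
            "index_table.csv": lambda p: io.write_table(p, index_table),
            "normalization.json": lambda p: io.write_json(
                p, norm_stats.reset_index().to_dict(orient="records")  # type: ignore[arg-type]
            ),
            "trend_table.csv": lambda p: io.write_table(p, trend_table),
            "features.csv": lambda p: io.write_table(
                p, features.data.reset_index()
            ),
            "assignments.csv": lambda p: io.write_table(
                p, result.assignment.rename_axis("municipality_id").reset_index()
            ),
            "linkage.csv": lambda p: io.write_table(
                p,
                pd.DataFrame(
                    result.linkage_matrix,
                    columns=["child_a", "child_b", "height", "size"],
                ),
            ),
            "profiles.csv": lambda p: io.write_table(
                p, result.profiles.reset_index()
            ),
            "composition.csv": lambda p: io.write_table(
                p, result.composition.reset_index()
            ),
            "profile_signs.csv": lambda p: io.write_table(
                p, sign_summary(result.profiles).reset_index()
            ),
        }
        for ncp in config.ncps:
            sub = trend_table[trend_table["ncp"] == ncp]
            artifacts[f"plot_data_{ncp}.csv"] = (
                lambda p, sub=sub: io.write_table(p, bubble_plot_data(sub))
            )
        for name, writer in artifacts.items():
            path = writer(output_dir / name)
            manifest["artifacts"][name] = io.file_sha256(path)
        if config.write_rasters:
            io.write_stack(output_dir / "rasters", stack)
            io.write_econ_tables(output_dir / "rasters" / "econ_tables.csv", econ)
        if config.write_geojson:
            props = result.assignment.to_frame()
            path = io.write_zones_geojson(
                output_dir / "zones.geojson", stack.zones, stack.pixel_size, props
            )
            manifest["artifacts"]["zones.geojson"] = io.file_sha256(path)
        io.write_json(output_dir / "manifest.json", manifest)

    return PipelineResult(
        stack=stack,
        econ=econ,
        ncp_table=ncp_table,
        index_table=index_table,
        normalization=norm_stats,
        trend_table=trend_table,
        features=features,
        clusters=result,
        manifest=manifest,
        output_dir=output_dir,
    )
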