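"""Readers and writers for all pipeline artifacts.

Rasters use the ESRI ASCII grid format (plain text, one file per timestep),
municipality zones go to GeoJSON (polygons dissolved from pixel squares),
tables to CSV, configuration to YAML, and the run manifest plus the
normalization sidecar to JSON. Every writer has a matching reader and the
pair round-trips values exactly at the written precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .types import EconTables, InputError, LandscapeStack

NODATA = -9999


# ---------------------------------------------------------------- rasters

def write_ascii_grid(path: str | Path, array: np.ndarray, pixel_size: float) -> Path:
    """Write a 2-D array as an ESRI ASCII grid (origin at the lower-left)."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise InputError("ASCII grids are 2-D; write one file per timestep")
    path = Path(path)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {pixel_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    fmt = "%d" if np.issubdtype(arr.dtype, np.integer) else "%.17g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array, cellsize)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    expected = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expected:
        raise InputError(f"{path.name}: grid shape {data.shape} != header {expected}")
    return data, header["cellsize"]


# ----------------------------------------------------------------- zones

def zone_polygons(zones: np.ndarray, pixel_size: float) -> dict[int, Any]:
    """Dissolve pixel squares into one (multi)polygon per municipality."""
    h, w = zones.shape
    polys: dict[int, Any] = {}
    for zid in np.unique(zones):
        rows, cols = np.nonzero(zones == zid)
        boxes = [
            box(c * pixel_size, (h - 1 - r) * pixel_size,
                (c + 1) * pixel_size, (h - r) * pixel_size)
            for r, c in zip(rows, cols)
        ]
        polys[int(zid)] = unary_union(boxes)
    return polys


def write_zones_geojson(
    path: str | Path,
    zones: np.ndarray,
    pixel_size: float,
    properties: pd.DataFrame | None = None,
) -> Path:
    """Write municipality polygons (plus optional per-zone properties)."""
    path = Path(path)
    features = []
    for zid, geom in zone_polygons(zones, pixel_size).items():
        props: dict[str, Any] = {"municipality_id": zid}
        if properties is not None and zid in properties.index:
            props.update(
                {k: _jsonable(v) for k, v in properties.loc[zid].items()}
            )
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    payload = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(payload))
    return path


def _jsonable(value: Any) -> Any:
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


# ------------------------------------------------------- landscape stack

_STATIC_RASTERS = ("protection", "precipitation", "pet", "zones")


def write_stack(directory: str | Path, stack: LandscapeStack) -> Path:
    """Write every raster of a landscape stack as ASCII grids + metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    px = stack.pixel_size
    for t, label in enumerate(stack.timestep_labels):
        write_ascii_grid(directory / f"land_cover_{label}.asc", stack.land_cover[t], px)
        write_ascii_grid(directory / f"population_{label}.asc", stack.population[t], px)
        for name, layer in stack.threat_layers.items():
            write_ascii_grid(directory / f"threat_{name}_{label}.asc", layer[t], px)
    for name in _STATIC_RASTERS:
        write_ascii_grid(directory / f"{name}.asc", getattr(stack, name), px)
    meta = {
        "timestep_labels": list(stack.timestep_labels),
        "threat_names": sorted(stack.threat_layers),
        "pixel_area": stack.pixel_area,
        "crs": stack.crs,
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_stack(directory: str | Path) -> LandscapeStack:
    """Read a landscape stack written by :func:`write_stack`."""
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    labels = meta["timestep_labels"]

    def series(prefix: str) -> np.ndarray:
        layers = []
        for label in labels:
            path = directory / f"{prefix}_{label}.asc"
            if not path.exists():
                raise InputError(f"missing timestep raster {path.name}")
            layers.append(read_ascii_grid(path)[0])
        return np.stack(layers)

    land_cover = series("land_cover").astype(np.int8)
    population = series("population")
    threats = {name: series(f"threat_{name}") for name in meta["threat_names"]}
    static = {
        name: read_ascii_grid(directory / f"{name}.asc")[0]
        for name in _STATIC_RASTERS
    }
    return LandscapeStack(
        land_cover=land_cover,
        population=population,
        protection=static["protection"].astype(np.int8),
        threat_layers=threats,
        precipitation=static["precipitation"],
        pet=static["pet"],
        zones=static["zones"].astype(np.int32),
        pixel_area=meta["pixel_area"],
        timestep_labels=tuple(labels),
        crs=meta.get("crs", "local-metric"),
    )


# ------------------------------------------------------------ econ tables

def write_econ_tables(path: str | Path, econ: EconTables) -> Path:
    """EconTables as a long CSV (table, key, timestep, value)."""
    rows = []
    for f in dataclasses.fields(econ):
        value = getattr(econ, f.name)
        if isinstance(value, dict):
            for key, v in value.items():
                rows.append({"table": f.name, "key": key, "value": float(v)})
        elif isinstance(value, tuple):
            for t, v in enumerate(value):
                rows.append({"table": f.name, "key": str(t), "value": float(v)})
        else:
            rows.append({"table": f.name, "key": "", "value": float(value)})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_econ_tables(path: str | Path) -> EconTables:
    df = pd.read_csv(path, keep_default_na=False)
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(EconTables):
        sub = df[df["table"] == f.name]
        if sub.empty:
            raise InputError(f"econ table CSV missing {f.name!r}")
        if f.type.startswith("dict"):
            kwargs[f.name] = dict(zip(sub["key"], sub["value"].astype(float)))
        elif f.type.startswith("tuple"):
            ordered = sub.sort_values("key", key=lambda s: s.astype(int))
            kwargs[f.name] = tuple(ordered["value"].astype(float))
        else:
            kwargs[f.name] = float(sub["value"].iloc[0])
    return EconTables(**kwargs)


# -------------------------------------------------------- tables and json

def write_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def write_yaml(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
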