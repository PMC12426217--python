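"""Zonal statistics over the municipality partition.

Pixels belong to exactly one zone (assignment by pixel center), so zonal
means and sums are exact bincount reductions; no area weighting is needed on
a uniform grid.
"""

from __future__ import annotations

import numpy as np


def zone_counts(zones: np.ndarray, n_zones: int | None = None) -> np.ndarray:
    """Pixel count per zone."""
    if n_zones is None:
        n_zones = int(zones.max()) + 1
    return np.bincount(zones.ravel(), minlength=n_zones)


def zone_sum(
    values: np.ndarray, zones: np.ndarray, n_zones: int | None = None
) -> np.ndarray:
    """Sum of a pixel field per zone."""
    if n_zones is None:
        n_zones = int(zones.max()) + 1
    return np.bincount(
        zones.ravel(), weights=values.ravel().astype(float), minlength=n_zones
    )


def zone_mean(
    values: np.ndarray, zones: np.ndarray, n_zones: int | None = None
) -> np.ndarray:
    """Mean of a pixel field per zone."""
    if n_zones is None:
        n_zones = int(zones.max()) + 1
    counts = zone_counts(zones, n_zones)
    with np.errstate(invalid="ignore"):
        out = zone_sum(values, zones, n_zones) / counts
    out[counts == 0] = 0.0
    return out


def class_area_per_zone(
    land_cover: np.ndarray,
    zones: np.ndarray,
    class_code: int,
    n_zones: int | None = None,
) -> np.ndarray:
    """Pixel count of one land-cover class per zone."""
    return zone_sum((land_cover == class_code).astype(float), zones, n_zones)
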