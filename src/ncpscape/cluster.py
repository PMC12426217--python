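"""Spatiotemporal archetype clustering of municipalities.

The feature matrix holds, per municipality, three variables for each NCP
(current budget, B_coeff, R_coeff) — 18 columns for the default six NCPs —
z-scored per column. Agglomerative clustering (Ward by default, Euclidean)
groups municipalities; the cluster count is either fixed or chosen by a
reproducible proxy for dendrogram inspection (mean silhouette, or the
largest relative merge-height gap). Cluster ids are canonical: ordered by
descending size, ties by the lowest member id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .types import LAND_COVER_CLASSES, ConfigurationError, InputError, LandscapeStack

FEATURE_VARS: tuple[str, ...] = ("current_budget", "b_coeff", "r_coeff")


@dataclass
class FeatureMatrix:
    """Municipality x feature matrix with its standardization record."""

    data: pd.DataFrame  # standardized values, index = municipality_id
    means: pd.Series  # per-column mean before standardization
    sds: pd.Series  # per-column sd before standardization

    @property
    def raw(self) -> pd.DataFrame:
        """Unstandardized feature values."""
        return self.data * self.sds + self.means


@dataclass
class ClusterResult:
    assignment: pd.Series  # municipality_id -> canonical cluster id (0-based)
    linkage_matrix: np.ndarray  # scipy linkage encoding of the merge tree
    k: int
    cut_height: float  # cutting the tree just below this height gives k groups
    profiles: pd.DataFrame | None = None  # per-cluster unstandardized feature means
    composition: pd.DataFrame | None = None  # per-cluster land-cover shares


def assemble_features(
    trend_table: pd.DataFrame,
    standardize: bool = True,
    on_constant: str = "error",
) -> FeatureMatrix:
    """Pivot the trend table into the municipality x (3 x n_NCP) matrix.

    Column order is deterministic (NCPs alphabetical, then the three trend
    variables). A constant column cannot be z-scored; by default that is an
    error, ``on_constant="zero"`` maps it to zeros instead.
    """
    missing = trend_table[FEATURE_VARS[0]].isna()
    if missing.any():
        raise InputError("trend table contains missing values")
    wide = trend_table.pivot(
        index="municipality_id", columns="ncp", values=list(FEATURE_VARS)
    )
    if wide.isna().any().any():
        gaps = wide.isna().any(axis=1)
        bad = wide.index[gaps].tolist()
        raise InputError(f"municipalities missing NCP records: {bad}")
    wide.columns = [f"{ncp}_{var}" for var, ncp in wide.columns]
    wide = wide[sorted(wide.columns)]
    means = wide.mean()
    sds = wide.std(ddof=0)
    if not standardize:
        return FeatureMatrix(data=wide, means=means * 0.0, sds=sds * 0.0 + 1.0)
    constant = sds <= 0
    if constant.any():
        names = sds.index[constant].tolist()
        if on_constant == "error":
            raise InputError(f"constant feature columns cannot be z-scored: {names}")
        sds = sds.where(~constant, 1.0)
    data = (wide - means) / sds
    if constant.any():
        data.loc[:, constant[constant].index] = 0.0
    return FeatureMatrix(data=data, means=means, sds=sds)


def _canonical_labels(raw_labels: np.ndarray, index: pd.Index) -> pd.Series:
    """Relabel clusters 0..k-1 by descending size, ties by lowest member id."""
    order = sorted(
        np.unique(raw_labels),
        key=lambda c: (-(raw_labels == c).sum(), index[raw_labels == c].min()),
    )
    mapping = {old: new for new, old in enumerate(order)}
    return pd.Series(
        [mapping[c] for c in raw_labels], index=index, name="cluster"
    )


def hierarchical_cluster(
    features: FeatureMatrix, linkage_method: str = "ward", k: int = 4
) -> ClusterResult:
    """Cut the agglomerative tree into ``k`` groups."""
    if linkage_method not in ("ward", "average", "complete"):
        raise ConfigurationError(f"unsupported linkage {linkage_method!r}")
    n = len(features.data)
    if k > n:
        raise InputError(f"k={k} exceeds {n} municipalities")
    z = linkage(features.data.to_numpy(), method=linkage_method, metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    heights = z[:, 2]
    # cutting at the height of the last merge *included* leaves k groups
    cut_height = float(heights[n - k - 1]) if k < n else 0.0
    return ClusterResult(
        assignment=_canonical_labels(raw, features.data.index),
        linkage_matrix=z,
        k=int(len(np.unique(raw))),
        cut_height=cut_height,
    )


def select_k(
    features: FeatureMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    method: str = "silhouette",
    linkage_method: str = "ward",
) -> int:
    """Reproducible proxy for dendrogram inspection.

    ``silhouette`` maximizes the mean silhouette over tree cuts;
    ``merge_gap`` picks the cut below the largest relative jump in merge
    heights. Ties go to the smaller k.
    """
    if not k_range:
        raise InputError("empty k_range")
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) == 1:
        return ks[0]
    x = features.data.to_numpy()
    z = linkage(x, method=linkage_method, metric="euclidean")
    if method == "silhouette":
        best_k, best_score = ks[0], -np.inf
        for k in ks:
            labels = fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(x, labels, metric="euclidean")
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        return best_k
    if method == "merge_gap":
        heights = z[:, 2]
        n = x.shape[0]
        best_k, best_gap = ks[0], -np.inf
        for k in ks:
            if k >= n:
                continue
            below, above = heights[-k], heights[-(k - 1)] if k > 1 else np.inf
            gap = (above - below) / below if below > 0 else np.inf
            if gap > best_gap + 1e-12:
                best_k, best_gap = k, gap
        return best_k
    raise ConfigurationError(f"unknown k-selection method {method!r}")


def profile_clusters(
    result: ClusterResult,
    features: FeatureMatrix,
    stack: LandscapeStack | None = None,
) -> ClusterResult:
    """Attach per-cluster mean profiles (unstandardized) and, when a
    landscape is given, current-timestep land-cover composition shares."""
    raw = features.raw
    raw = raw.assign(cluster=result.assignment)
    profiles = raw.groupby("cluster").mean()
    profiles["n_municipalities"] = result.assignment.value_counts().sort_index()
    result.profiles = profiles
    if stack is not None:
        lc = stack.land_cover[-1]
        n_zones = stack.n_zones
        zone_cluster = result.assignment.reindex(range(n_zones)).to_numpy()
        rows = {}
        for c in sorted(result.assignment.unique()):
            mask = np.isin(stack.zones, np.flatnonzero(zone_cluster == c))
            total = mask.sum()
            rows[c] = {
                name: float((lc[mask] == code).sum()) / total
                for code, name in enumerate(LAND_COVER_CLASSES)
            }
        result.composition = pd.DataFrame.from_dict(rows, orient="index")
        result.composition.index.name = "cluster"
    return result


def sign_summary(profiles: pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """Machine-readable sign pattern (+/-/0) of each cluster's profile."""
    numeric = profiles.drop(columns=["n_municipalities"], errors="ignore")
    signs = numeric.map(
        lambda v: "+" if v > epsilon else ("-" if v < -epsilon else "0")
    )
    return signs
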