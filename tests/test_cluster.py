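"""Feature assembly, Ward clustering, k selection and cluster profiling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

from ncpscape import PipelineConfig, run_pipeline
from ncpscape.cluster import (
    FeatureMatrix,
    assemble_features,
    hierarchical_cluster,
    profile_clusters,
    select_k,
)
from ncpscape.synth import planted_labels
from ncpscape.types import InputError


def _trend_table(n_munis=10, ncps=("POL", "WAT"), rng=None):
    rng = rng or np.random.default_rng(4)
    rows = []
    for m in range(n_munis):
        for ncp in ncps:
            rows.append(
                {
                    "municipality_id": m,
                    "ncp": ncp,
                    "current_budget": rng.normal(),
                    "b_coeff": rng.normal(),
                    "r_coeff": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def _feature_matrix(points: np.ndarray) -> FeatureMatrix:
    df = pd.DataFrame(points, columns=[f"f{i}" for i in range(points.shape[1])])
    df.index.name = "municipality_id"
    return FeatureMatrix(
        data=df, means=df.mean() * 0.0, sds=df.std(ddof=0) * 0.0 + 1.0
    )


def test_assemble_features_shape_and_standardization():
    tt = _trend_table(n_munis=12, ncps=("POL", "HAB", "REC", "FOD", "WAT", "CLI"))
    fm = assemble_features(tt)
    assert fm.data.shape == (12, 18)  # 3 variables per NCP per municipality
    np.testing.assert_allclose(fm.data.mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(fm.data.std(ddof=0), 1.0, atol=1e-12)
    # the standardization record inverts exactly
    tt_row = tt[(tt.municipality_id == 3) & (tt.ncp == "WAT")].iloc[0]
    assert fm.raw.loc[3, "WAT_b_coeff"] == pytest.approx(tt_row.b_coeff)


def test_assemble_features_missing_ncp_is_named():
    tt = _trend_table(n_munis=4)
    tt = tt[~((tt.municipality_id == 2) & (tt.ncp == "WAT"))]
    with pytest.raises(InputError, match="2"):
        assemble_features(tt)


def test_assemble_features_constant_column_policy():
    tt = _trend_table(n_munis=6)
    tt.loc[tt.ncp == "POL", "r_coeff"] = 0.5
    with pytest.raises(InputError, match="POL_r_coeff"):
        assemble_features(tt)
    fm = assemble_features(tt, on_constant="zero")
    assert (fm.data["POL_r_coeff"] == 0.0).all()


def test_trivial_cuts():
    points = np.random.default_rng(1).normal(size=(8, 3))
    fm = _feature_matrix(points)
    singletons = hierarchical_cluster(fm, k=8)
    assert singletons.assignment.nunique() == 8
    lumped = hierarchical_cluster(fm, k=1)
    assert lumped.assignment.nunique() == 1
    with pytest.raises(InputError):
        hierarchical_cluster(fm, k=9)


def test_two_separated_clouds_recovered_exactly():
    """Separation >> spread: Ward must match the nearest-centroid oracle."""
    rng = np.random.default_rng(2)
    a = rng.normal(size=(5, 2)) * 0.1
    b = rng.normal(size=(5, 2)) * 0.1 + 50.0
    fm = _feature_matrix(np.vstack([a, b]))
    result = hierarchical_cluster(fm, k=2)
    centroids = np.array([[0.0, 0.0], [50.0, 50.0]])
    oracle = np.argmin(
        ((fm.data.to_numpy()[:, None, :] - centroids) ** 2).sum(-1), axis=1
    )
    # canonical ids may differ from oracle ids; compare the partitions
    got = [frozenset(np.flatnonzero(result.assignment.to_numpy() == c)) for c in (0, 1)]
    want = [frozenset(np.flatnonzero(oracle == c)) for c in (0, 1)]
    assert set(got) == set(want)


def test_ward_merge_heights_nondecreasing_and_cut_reproduces():
    tt = _trend_table(n_munis=20, ncps=("POL", "HAB", "WAT"))
    fm = assemble_features(tt)
    result = hierarchical_cluster(fm, k=4)
    heights = result.linkage_matrix[:, 2]
    assert (np.diff(heights) >= -1e-12).all()
    by_distance = fcluster(result.linkage_matrix, t=result.cut_height, criterion="distance")
    # same partition as the recorded assignment
    df = pd.DataFrame({"a": result.assignment.to_numpy(), "b": by_distance})
    assert df.groupby("a")["b"].nunique().max() == 1
    assert df.groupby("b")["a"].nunique().max() == 1


def test_assignment_invariant_under_row_permutation():
    tt = _trend_table(n_munis=15, ncps=("POL", "WAT", "CLI"))
    base = hierarchical_cluster(assemble_features(tt), k=3).assignment
    shuffled = tt.sample(frac=1.0, random_state=9)
    permuted = hierarchical_cluster(assemble_features(shuffled), k=3).assignment
    pd.testing.assert_series_equal(base.sort_index(), permuted.sort_index())


def test_select_k_forced_and_single_blob():
    fm = _feature_matrix(np.random.default_rng(3).normal(size=(20, 4)))
    assert select_k(fm, k_range=(3,)) == 3
    with pytest.raises(InputError):
        select_k(fm, k_range=())
    # one Gaussian blob: silhouette prefers the smallest k in the range
    assert select_k(fm, k_range=(2, 3, 4, 5)) == 2


def test_select_k_recovers_planted_count(small_spec):
    cfg = PipelineConfig(
        region={
            "n_municipalities": small_spec.n_municipalities,
            "grid_shape": list(small_spec.grid_shape),
            "population_total": small_spec.population_total,
            "seed": small_spec.seed,
        },
        output_dir=None,
    )
    res = run_pipeline(cfg)
    assert select_k(res.features) == 4


def test_profiles_and_composition(small_spec):
    cfg = PipelineConfig(
        region={
            "n_municipalities": small_spec.n_municipalities,
            "grid_shape": list(small_spec.grid_shape),
            "population_total": small_spec.population_total,
            "seed": small_spec.seed,
        },
        output_dir=None,
        clustering={"k": 4},
    )
    res = run_pipeline(cfg)
    result, fm, stack = res.clusters, res.features, res.stack
    # pooled mean identity: overall mean = size-weighted mean of profiles
    sizes = result.profiles["n_municipalities"]
    numeric = result.profiles.drop(columns="n_municipalities")
    pooled = (numeric.mul(sizes, axis=0)).sum() / sizes.sum()
    np.testing.assert_allclose(pooled, fm.raw.mean(), atol=1e-9)
    # composition shares sum to 1 per cluster
    np.testing.assert_allclose(result.composition.sum(axis=1), 1.0, atol=1e-12)
    # the planted urbanizing archetype has the highest settlement share
    labels = planted_labels(small_spec)
    urban_cluster = (
        pd.Series(result.assignment.to_numpy())
        .groupby(pd.Series(labels))
        .agg(lambda s: s.mode().iloc[0])[0]
    )
    assert result.composition["settlement"].idxmax() == urban_cluster


def test_singleton_cluster_profile_equals_its_row():
    tt = _trend_table(n_munis=5, ncps=("POL",))
    fm = assemble_features(tt)
    result = hierarchical_cluster(fm, k=5)
    result = profile_clusters(result, fm)
    for muni, cluster_id in result.assignment.items():
        row = fm.raw.loc[muni]
        prof = result.profiles.loc[cluster_id].drop("n_municipalities")
        np.testing.assert_allclose(prof.to_numpy(), row.to_numpy(), atol=1e-12)
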