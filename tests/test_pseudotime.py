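"""Screening, pseudo-time construction and trend clustering tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from pmikit import (
    SynthConfig,
    benjamini_hochberg,
    build_pseudotime,
    cluster_trajectories,
    generate_cohort,
    label_trends,
    spearman_screen,
)
from pmikit.preprocessing import preprocess_table
from pmikit.pseudotime import PseudoTimeError, PseudoTimeSeries, bh_adjusted


# ---------------------------------------------------------------------------
# Spearman screening
# ---------------------------------------------------------------------------

def test_perfect_monotone_activation_has_rho_one():
    pmi = np.array([1, 2, 2, 3, 5, 5, 8, 13])
    res = spearman_screen(pmi[:, None].astype(float), pmi)
    assert res.table["rho"].iloc[0] == pytest.approx(1.0, abs=1e-12)
    assert res.table["selected"].iloc[0]


def test_rank_invariance_under_monotone_transform():
    pmi = np.arange(1, 21)
    res = spearman_screen(np.exp(pmi / 3.0)[:, None], pmi)
    assert res.table["rho"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_constant_activation_flagged_and_excluded(rng):
    A = np.column_stack([np.full(30, 2.0), rng.normal(size=30)])
    res = spearman_screen(A, rng.integers(1, 14, size=30))
    assert res.table["constant"].iloc[0]
    assert not res.table["selected"].iloc[0]
    assert np.isnan(res.table["rho"].iloc[0])


def test_screen_matches_scipy_per_column(rng):
    A = rng.normal(size=(40, 15))
    pmi = rng.integers(1, 14, size=40)
    res = spearman_screen(A, pmi)
    for j in range(15):
        rho, p = stats.spearmanr(A[:, j], pmi)
        assert res.table["rho"].iloc[j] == pytest.approx(rho, abs=1e-10)
        assert res.table["p_value"].iloc[j] == pytest.approx(p, abs=1e-10, rel=1e-7)


def test_misaligned_inputs_rejected(rng):
    with pytest.raises(PseudoTimeError):
        spearman_screen(rng.normal(size=(10, 2)), np.arange(5))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_step_up_example():
    rej = benjamini_hochberg(np.array([0.001, 0.5, 0.9]), alpha=0.05)
    np.testing.assert_array_equal(rej, [True, False, False])


def test_bh_extremes():
    assert benjamini_hochberg(np.zeros(5), 0.05).all()
    assert not benjamini_hochberg(np.ones(5), 0.05).any()


def test_bh_out_of_range_rejected():
    with pytest.raises(PseudoTimeError):
        benjamini_hochberg(np.array([0.5, 1.5]), 0.05)


@pytest.mark.parametrize("seed", [0, 1])
def test_bh_matches_statsmodels(rng, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=500) ** 2
    reject_sm, p_adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
    np.testing.assert_array_equal(benjamini_hochberg(p, 0.05), reject_sm)
    np.testing.assert_allclose(bh_adjusted(p), p_adj_sm, atol=1e-12)


# ---------------------------------------------------------------------------
# pseudo-time construction
# ---------------------------------------------------------------------------

def _std_table(values, pmi):
    from pmikit import FeatureTable

    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return FeatureTable(
        pd.DataFrame(values, index=[f"s{i}" for i in range(n)], columns=[f"f{j}" for j in range(m)]),
        pd.DataFrame(
            {"pmi_days": pmi, "sex": "male", "platform": "p"},
            index=[f"s{i}" for i in range(n)],
        ),
        pd.DataFrame({"mz_median": 100.0, "rt_median": 10.0}, index=[f"f{j}" for j in range(m)]),
        standardized=True,
    )


def test_single_sample_days_pass_through():
    table = _std_table([[1.0], [2.0], [3.0]], [1, 2, 3])
    pts = build_pseudotime(table, ["f0"], min_count=1)
    np.testing.assert_array_equal(pts.values.to_numpy(), [[1.0, 2.0, 3.0]])


def test_same_day_samples_are_averaged():
    table = _std_table([[1.0], [3.0], [7.0]], [3, 3, 4])
    pts = build_pseudotime(table, ["f0"], min_count=1)
    assert pts.values.loc["f0", 3] == 2.0
    assert pts.counts[3] == 2


def test_matches_brute_force_group_by(rng):
    values = rng.normal(size=(60, 5))
    pmi = rng.integers(1, 8, size=60)
    table = _std_table(values, pmi)
    pts = build_pseudotime(table, [f"f{j}" for j in range(5)], min_count=1)
    for day in np.unique(pmi):
        expected = values[pmi == day].mean(axis=0)
        np.testing.assert_allclose(pts.values[day].to_numpy(), expected, atol=1e-12)


def test_sample_order_permutation_invariance(rng):
    values = rng.normal(size=(50, 4))
    pmi = rng.integers(1, 6, size=50)
    perm = rng.permutation(50)
    a = build_pseudotime(_std_table(values, pmi), ["f0", "f1"], min_count=1)
    b = build_pseudotime(_std_table(values[perm], pmi[perm]), ["f0", "f1"], min_count=1)
    np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-12)


def test_min_count_and_filter_errors(rng):
    table = _std_table(rng.normal(size=(10, 2)), [1] * 9 + [2])
    pts = build_pseudotime(table, ["f0"], min_count=5)
    assert list(pts.pmi_grid) == [1]  # day 2 has a single sample
    with pytest.raises(PseudoTimeError):
        build_pseudotime(table, ["f0"], pmi_filter=(40, 50))
    with pytest.raises(PseudoTimeError):
        build_pseudotime(table, ["nope"])


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _pts(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"f{j}" for j in range(values.shape[0])]
    grid = np.arange(1, values.shape[1] + 1)
    return PseudoTimeSeries(
        values=pd.DataFrame(values, index=pd.Index(ids, name="feature_id"), columns=grid),
        counts=pd.Series(10, index=grid),
    )


def naive_ward_partitions(X):
    """Brute-force agglomerative Ward: recompute all pairwise merge costs
    each step; returns the partition at every cluster count."""
    clusters = [[i] for i in range(len(X))]
    partitions = {len(clusters): [list(c) for c in clusters]}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
                d = len(a) * len(b) / (len(a) + len(b)) * ((ma - mb) ** 2).sum()
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions[len(clusters)] = [list(c) for c in clusters]
    return partitions


def _labels_from_partition(partition, n):
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(partition):
        labels[members] = cid
    return labels


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clustering_matches_naive_ward_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(8, 6))
    pts = _pts(X)
    oracle = naive_ward_partitions(X)
    for k in range(1, 9):
        clusters = cluster_trajectories(pts, k=k, zscore_rows=False)
        got = clusters.assignments.to_numpy()
        expected = _labels_from_partition(oracle[k], 8)
        assert adjusted_rand_score(got, expected) == 1.0 or k == 8


def test_replicated_archetypes_perfectly_partitioned():
    grid = np.linspace(0, 1, 10)
    arch = np.stack([-grid, grid, np.cos(2 * np.pi * grid)])
    X = np.repeat(arch, 10, axis=0)
    truth = np.repeat([0, 1, 2], 10)
    clusters = cluster_trajectories(_pts(X), k=3)
    assert adjusted_rand_score(clusters.assignments.to_numpy(), truth) == 1.0


def test_k_one_and_k_too_large():
    pts = _pts(np.random.default_rng(0).normal(size=(5, 4)))
    assert cluster_trajectories(pts, k=1).assignments.nunique() == 1
    with pytest.raises(PseudoTimeError):
        cluster_trajectories(pts, k=6)


def test_newick_export_contains_all_leaves():
    pts = _pts(np.random.default_rng(0).normal(size=(5, 4)))
    nwk = cluster_trajectories(pts, k=2).to_newick()
    assert nwk.endswith(";")
    for fid in pts.values.index:
        assert fid in nwk


# ---------------------------------------------------------------------------
# trend labelling
# ---------------------------------------------------------------------------

def test_monotone_and_fluctuating_labels():
    grid = np.linspace(0, 1, 13)
    X = np.stack([-grid, -grid * 2, grid, grid * 2, np.cos(2 * np.pi * grid), np.cos(2 * np.pi * grid) + 0.1])
    pts = _pts(X)
    clusters = label_trends(cluster_trajectories(pts, k=3), pts)
    labels = clusters.feature_labels()
    assert list(labels) == [
        "decreasing",
        "decreasing",
        "increasing",
        "increasing",
        "fluctuating",
        "fluctuating",
    ]


def test_planted_trends_recovered_on_default_cohort(default_prepared):
    """End-to-end recovery at the default study scale: screening keeps
    the planted informative features (low false selection among noise),
    and clustering + labelling reproduces the planted trend classes."""
    std, truth = default_prepared["std"], default_prepared["truth"]
    screen = spearman_screen(std.values(), std.pmi, feature_ids=std.feature_ids)
    selected = set(screen.selected_ids)
    informative = truth.informative_ids()
    noise_ids = truth.feature_class.index[truth.feature_class == "noise"]
    assert np.mean([f in selected for f in informative]) >= 0.9
    assert np.mean([f in selected for f in noise_ids]) <= 2 * screen.alpha

    pts = build_pseudotime(std, informative, pmi_filter=(1, 13), min_count=5)
    clusters = label_trends(cluster_trajectories(pts, k=3), pts)
    labels = clusters.feature_labels()
    agreement = (labels == truth.feature_class[labels.index]).mean()
    assert agreement >= 0.9
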