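"""Screen statistics: z-scoring, energy tests, corrections, scores, transfer."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from pmulti.screen import (
    ScreenConfig,
    channel_intensity_score,
    differential_expression,
    energy_distance,
    energy_permutation_test,
    geneset_score,
    holm_sidak_adjust,
    knn_label_transfer,
    merge_clusters_by_de,
    pseudobulk_effects_and_correlations,
    screen_perturbations,
    zscore_vs_controls,
)


# -- z-scoring ---------------------------------------------------------------

def test_controls_standardize_per_batch(rng):
    X = rng.normal(5, 2, size=(100, 4))
    ctrl = np.zeros(100, bool)
    ctrl[:40] = True
    Z = zscore_vs_controls(X, ctrl)
    assert np.allclose(Z[ctrl].mean(axis=0), 0, atol=1e-12)
    assert np.allclose(Z[ctrl].std(axis=0), 1, atol=1e-12)


def test_two_batch_zscore_matches_manual_oracle(rng):
    X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 3, (30, 3))])
    batches = np.array(["b1"] * 30 + ["b2"] * 30)
    ctrl = np.tile([True] * 10 + [False] * 20, 2)
    Z = zscore_vs_controls(X, ctrl, batches)
    for b in ("b1", "b2"):
        sel = batches == b
        mu = X[sel & ctrl].mean(axis=0)
        sd = X[sel & ctrl].std(axis=0)
        assert np.allclose(Z[sel], (X[sel] - mu) / sd)


def test_zscore_error_and_degenerate_cases():
    X = np.ones((4, 2))
    with pytest.raises(ValueError, match="batch"):
        zscore_vs_controls(X, np.array([True, False, False, False]),
                           np.array(["a", "a", "b", "b"]))
    with pytest.warns(UserWarning, match="zero control sd"):
        Z = zscore_vs_controls(X, np.array([True, True, False, False]))
    assert (Z == 0).all()


# -- energy distance ---------------------------------------------------------

def test_energy_distance_closed_forms():
    assert energy_distance([0.0], [3.0]) == pytest.approx(6.0)
    assert energy_distance([0.0, 2.0], [1.0, 3.0]) == pytest.approx(1.0)
    assert energy_distance([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)


def test_energy_distance_matches_scipy_univariate(rng):
    """scipy's 1-D energy distance squared equals the V-statistic."""
    for _ in range(5):
        a, b = rng.normal(size=12), rng.normal(1, 2, size=9)
        ours = energy_distance(a, b)
        assert ours == pytest.approx(scipy.stats.energy_distance(a, b) ** 2)
        assert ours >= 0


def test_energy_distance_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        energy_distance(np.ones((3, 2)), np.ones((3, 3)))


def test_exhaustive_permutation_exact_tail():
    # well-separated pairs: only the identity and its complement reach E_obs
    E, p = energy_permutation_test(
        np.array([[0.0], [0.1]]), np.array([[10.0], [10.1]]), method="exhaustive"
    )
    assert E == pytest.approx(2 * 10.0 - 0.05 - 0.05, rel=1e-3)
    assert p == pytest.approx(2 / 6)


def test_sampled_permutation_deterministic_under_seed(rng):
    a, b = rng.normal(size=(10, 3)), rng.normal(0.5, 1, size=(20, 3))
    r1 = energy_permutation_test(a, b, n_permutations=200, seed=7, method="sampled")
    r2 = energy_permutation_test(a, b, n_permutations=200, seed=7, method="sampled")
    assert r1 == r2
    with pytest.raises(ValueError):
        energy_permutation_test(a, b, n_permutations=0)


def test_null_pvalues_roughly_uniform(rng):
    """Same-distribution groups reject at about the nominal rate."""
    n_rep, alpha = 200, 0.05
    rejects = 0
    for i in range(n_rep):
        a = rng.normal(size=(15, 2))
        b = rng.normal(size=(30, 2))
        _, p = energy_permutation_test(a, b, n_permutations=99, seed=i,
                                       method="sampled")
        rejects += p < alpha
    se = np.sqrt(alpha * (1 - alpha) / n_rep)
    assert rejects / n_rep < alpha + 4 * se


# -- multiple testing --------------------------------------------------------

def test_holm_sidak_closed_form_and_edges():
    assert np.allclose(
        holm_sidak_adjust([0.01, 0.04, 0.5]), [0.029701, 0.0784, 0.5]
    )
    assert holm_sidak_adjust([0.2]) == pytest.approx([0.2])
    assert (holm_sidak_adjust([0.0, 0.0]) == 0).all()
    with pytest.raises(ValueError):
        holm_sidak_adjust([1.2])


def test_holm_sidak_agrees_with_statsmodels(rng):
    for _ in range(10):
        p = rng.random(rng.integers(1, 12))
        ours = holm_sidak_adjust(p)
        ref = multipletests(p, method="holm-sidak")[1]
        assert np.allclose(ours, ref)
        assert (ours >= p - 1e-15).all()


# -- differential expression -------------------------------------------------

def test_mannwhitney_exact_small_sample():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    res = differential_expression(X, np.array([1, 1, 0, 0], bool),
                                  np.array([0, 0, 1, 1], bool))
    assert res["p"].iloc[0] == pytest.approx(1 / 3)


def test_identical_groups_yield_no_rejections(rng):
    X = np.tile(rng.normal(size=(1, 6)), (20, 1))
    res = differential_expression(X, np.arange(20) < 10, np.arange(20) >= 10)
    assert (res["p"] == 1).all()
    assert not res["significant"].any()


def test_de_detects_shift_and_equalize_subsamples(rng):
    X = np.vstack([rng.normal(0, 1, (50, 5)), rng.normal(2, 1, (200, 5))])
    X[:, -1] = 0.0  # constant feature -> p = 1
    g = np.arange(250) < 50
    res = differential_expression(X, g, ~g)
    assert res["significant"].iloc[:4].all()
    assert res["p"].iloc[4] == 1.0
    assert res["log2_fold_change"].iloc[0] < 0
    r1 = differential_expression(X, g, ~g, equalize_n=True, seed=1)
    r2 = differential_expression(X, g, ~g, equalize_n=True, seed=1)
    assert np.allclose(r1["p"], r2["p"])


# -- screen-level orchestration ----------------------------------------------

def test_screen_detects_shifted_perturbation(rng):
    n_ctrl, n_g = 150, 40
    X = np.vstack(
        [
            rng.normal(0, 1, (n_ctrl, 10)),
            rng.normal(0, 1, (n_g, 10)) + np.r_[np.full(5, 1.2), np.zeros(5)],
            rng.normal(0, 1, (n_g, 10)),
        ]
    )
    labels = np.array([None] * n_ctrl + ["hit"] * n_g + ["null"] * n_g, dtype=object)
    ctrl = np.arange(len(X)) < n_ctrl
    cfg = ScreenConfig(n_pcs=5, n_permutations=500, rng_seed=0)
    res = screen_perturbations(X, labels, ctrl, cfg)
    assert res.loc["hit", "significant"]
    assert not res.loc["null", "significant"]
    assert (res["adjusted_p"] >= res["raw_p"] - 1e-15).all()


# -- gene-set and channel scores ---------------------------------------------

def _score_setup(rng, shift=1.0, n_per=60):
    genes = [f"g{j}" for j in range(12)]
    gene_set = genes[:4]
    Z = rng.normal(size=(3 * n_per, 12))
    labels = np.array([None] * n_per + ["pert"] * n_per + ["other"] * n_per,
                      dtype=object)
    ctrl = np.arange(3 * n_per) < n_per
    Z[labels == "pert"] += shift * np.isin(genes, gene_set)
    return Z, genes, gene_set, labels, ctrl


def test_geneset_score_recovers_injected_shift(rng):
    Z, genes, gene_set, labels, ctrl = _score_setup(rng)
    res = geneset_score(Z, genes, gene_set, labels, ctrl)
    assert res.loc["pert", "score"] == pytest.approx(1.0, abs=0.15)
    assert res["score"].idxmax() == "pert"
    assert res.loc["pert", "significant"]


def test_geneset_score_single_gene_reduces_to_mean_z(rng):
    Z, genes, _, labels, ctrl = _score_setup(rng, shift=0.0)
    res = geneset_score(Z, genes, ["g3"], labels, ctrl)
    expected = Z[labels == "pert"][:, 3].mean()
    assert res.loc["pert", "score"] == pytest.approx(expected)
    with pytest.raises(ValueError):
        geneset_score(Z, genes, [], labels, ctrl)
    with pytest.warns(UserWarning, match="missing"):
        geneset_score(Z, genes, ["g3", "nope"], labels, ctrl)


def test_channel_score_flags_scaled_channel(rng):
    n = 80
    channels = ["ch0", "ch1", "ch2"]
    raw = rng.lognormal(3, 0.3, size=(3 * n, 3))
    labels = np.array([None] * n + ["ko"] * n + ["other"] * n, dtype=object)
    ctrl = np.arange(3 * n) < n
    raw[labels == "ko", 1] *= 0.5
    Z = zscore_vs_controls(raw, ctrl)
    res = channel_intensity_score(Z, channels, labels, ctrl)
    ko = res[res["perturbation"] == "ko"].set_index("channel")
    assert ko["score"].idxmin() == "ch1"
    assert ko.loc["ch1", "significant"]
    # constant offsets on the raw scale are absorbed by control z-scoring
    Z2 = zscore_vs_controls(raw + 100.0, ctrl)
    res2 = channel_intensity_score(Z2, channels, labels, ctrl)
    assert np.allclose(res2["score"], res["score"])


# -- pseudobulk correlations -------------------------------------------------

def test_pseudobulk_correlations_structure(rng):
    n = 40
    base = rng.normal(size=(4 * n, 30))
    program = np.zeros(30)
    program[:10] = 1.5
    labels = np.array(
        [None] * n + ["a1"] * n + ["a2"] * n + ["b"] * n, dtype=object
    )
    ctrl = np.arange(4 * n) < n
    base[np.isin(labels, ["a1", "a2"])] += program
    base[labels == "b"] -= program
    genes = [f"g{j}" for j in range(30)]
    eff, corr = pseudobulk_effects_and_correlations(
        base, labels, ctrl, genes, top_n=30
    )
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)
    assert corr.loc["a1", "a2"] > 0.8
    assert corr.loc["a1", "b"] < -0.8
    with pytest.warns(UserWarning, match="clipped"):
        pseudobulk_effects_and_correlations(base, labels, ctrl, genes, top_n=999)


def test_duplicated_group_correlates_perfectly(rng):
    n = 25
    block = rng.normal(size=(n, 10))
    X = np.vstack([rng.normal(size=(n, 10)), block, block])
    labels = np.array([None] * n + ["p1"] * n + ["p2"] * n, dtype=object)
    ctrl = np.arange(3 * n) < n
    _, corr = pseudobulk_effects_and_correlations(
        X, labels, ctrl, [f"g{j}" for j in range(10)], top_n=10
    )
    assert corr.loc["p1", "p2"] == pytest.approx(1.0)


# -- label transfer and cluster merging --------------------------------------

def test_knn_label_transfer_behaviors(rng):
    ref = np.vstack([rng.normal(0, 0.5, (500, 2)), rng.normal(8, 0.5, (500, 2))])
    lab = np.array(["L"] * 500 + ["R"] * 500, dtype=object)
    q = np.vstack([rng.normal(0, 0.5, (100, 2)), rng.normal(8, 0.5, (100, 2))])
    got = knn_label_transfer(ref, lab, q, k=10)
    truth = np.array(["L"] * 100 + ["R"] * 100, dtype=object)
    assert (got == truth).mean() >= 0.99
    # coincident identical-label references vote unanimously
    same = knn_label_transfer(np.zeros((10, 2)), np.array(["x"] * 10),
                              np.zeros((1, 2)), k=10)
    assert same[0] == "x"
    # k = 1 reduces to the nearest neighbor
    ref2 = np.array([[0.0], [10.0]])
    got2 = knn_label_transfer(ref2, np.array(["a", "b"]), np.array([[2.0]]), k=1)
    assert got2[0] == "a"
    with pytest.raises(ValueError):
        knn_label_transfer(np.zeros((0, 2)), np.array([]), np.zeros((1, 2)))


def test_cluster_merging_null_and_separated(rng):
    # two clusters drawn from one distribution collapse to one
    X = rng.normal(size=(120, 12))
    labels = np.array(["c1"] * 60 + ["c2"] * 60, dtype=object)
    merged = merge_clusters_by_de(X, labels, min_de_genes=10)
    assert len(set(merged)) == 1
    # strongly separated clusters survive and merging is idempotent
    X2 = X.copy()
    X2[60:] += 3.0
    kept = merge_clusters_by_de(X2, labels, min_de_genes=10)
    assert len(set(kept)) == 2
    assert (merge_clusters_by_de(X2, kept, min_de_genes=10) == kept).all()
    # a single cluster is returned unchanged
    single = np.array(["only"] * 120, dtype=object)
    assert (merge_clusters_by_de(X, single) == single).all()
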