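"""Phenotype statistics for pooled in vivo perturbation screens.

The screening statistic is the two-sample energy distance

    E(A, B) = 2 E||a - b|| - E||a - a'|| - E||b - b'||

computed between the cells of one perturbation and control cells in the
space of the top principal components, with significance from random
relabeling permutations and family-wise error control by Holm-Sidak.
Supporting statistics: batch-aware z-scoring against control cells,
Mann-Whitney differential expression (Benjamini-Hochberg), gene-set and
morphology-channel scores (Benjamini-Yekutieli), pseudobulk effect
correlations restricted to highly expressed genes, K-nearest-neighbor
label transfer, and merging of clusters lacking differential expression.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenConfig",
    "zscore_vs_controls",
    "energy_distance",
    "energy_permutation_test",
    "holm_sidak_adjust",
    "screen_perturbations",
    "differential_expression",
    "geneset_score",
    "channel_intensity_score",
    "pseudobulk_effects_and_correlations",
    "knn_label_transfer",
    "merge_clusters_by_de",
    "pca_scores",
]


@dataclass
class ScreenConfig:
    n_pcs: int = 20
    n_permutations: int = 10_000
    alpha: float = 0.05
    top_n_genes: int = 250
    min_de_genes_for_cluster: int = 10
    knn_k: int = 10
    equalize_n: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for f in ("n_pcs", "n_permutations", "top_n_genes",
                  "min_de_genes_for_cluster", "knn_k"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# z-scoring against controls

def zscore_vs_controls(
    X: np.ndarray,
    control_mask: np.ndarray,
    batch_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Z-score every cell against the control cells of its own batch.

    Per batch and per feature: z = (x - mean_ctrl) / sd_ctrl, with the
    moments taken over that batch's control cells only.  A batch without
    at least two control cells is an error; features with zero control
    sd get z = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if batch_labels is None:
        batch_labels = np.zeros(X.shape[0], dtype=int)
    batch_labels = np.asarray(batch_labels)
    Z = np.empty_like(X)
    warned = False
    for b in np.unique(batch_labels):
        sel = batch_labels == b
        ctrl = sel & control_mask
        if ctrl.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 control cells")
        mu = X[ctrl].mean(axis=0)
        sd = X[ctrl].std(axis=0)
        zero = sd == 0
        if zero.any() and not warned:
            warnings.warn(
                f"{int(zero.sum())} features with zero control sd; z set to 0",
                stacklevel=2,
            )
            warned = True
        sd_safe = np.where(zero, 1.0, sd)
        Z[sel] = (X[sel] - mu) / sd_safe
        Z[np.ix_(sel, zero)] = 0.0
    return Z


# ---------------------------------------------------------------------------
# energy distance and permutation testing

def energy_distance(A: np.ndarray, B: np.ndarray) -> float:
    """V-statistic energy distance between two point sets.

    Within-set means run over all ordered pairs including self-pairs, so
    the statistic is always non-negative and zero iff the multisets agree.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch between point sets")
    if len(A) == 0 or len(B) == 0:
        raise ValueError("point sets must be non-empty")
    ab = cdist(A, B).mean()
    aa = cdist(A, A).mean()
    bb = cdist(B, B).mean()
    return float(2.0 * ab - aa - bb)


def _energy_from_mask(D: np.ndarray, maskA: np.ndarray, T: float) -> float:
    nA = int(maskA.sum())
    nB = D.shape[0] - nA
    S_A = D[np.ix_(maskA, maskA)].sum()
    S_AB = D[maskA].sum() - S_A
    S_BB = T - S_A - 2.0 * S_AB
    return 2.0 * S_AB / (nA * nB) - S_A / nA**2 - S_BB / nB**2


def energy_permutation_test(
    cells_g: np.ndarray,
    cells_ctrl: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
    method: str = "auto",
    max_exhaustive: int = 5_000,
) -> tuple[float, float]:
    """Energy-distance permutation test between a group and controls.

    The null is built by randomly relabeling the pooled cells, preserving
    group sizes.  Sampled permutations use the +1 pseudocount
    p = (1 + #{E_perm >= E_obs}) / (1 + n_permutations); when the number
    of distinct partitions is at most `max_exhaustive` (or
    ``method="exhaustive"``), all partitions are enumerated and the exact
    tail probability (identity partition included, no pseudocount) is
    returned.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    A = np.asarray(cells_g, dtype=float)
    B = np.asarray(cells_ctrl, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch")
    nA, m = len(A), len(A) + len(B)
    pooled = np.vstack([A, B])
    D = cdist(pooled, pooled)
    T = D.sum()
    obs_mask = np.zeros(m, dtype=bool)
    obs_mask[:nA] = True
    E_obs = _energy_from_mask(D, obs_mask, T)

    n_part = comb(m, nA)
    if method == "exhaustive" or (method == "auto" and n_part <= max_exhaustive):
        count = 0
        for combo in itertools.combinations(range(m), nA):
            mask = np.zeros(m, dtype=bool)
            mask[list(combo)] = True
            if _energy_from_mask(D, mask, T) >= E_obs - 1e-12:
                count += 1
        return E_obs, count / n_part
    if method not in ("auto", "sampled"):
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    # (B, m) membership matrix of random size-nA subsets
    idx = rng.random((n_permutations, m)).argsort(axis=1)[:, :nA]
    P = np.zeros((n_permutations, m))
    np.put_along_axis(P, idx, 1.0, axis=1)
    PD = P @ D
    S_A = (PD * P).sum(axis=1)
    S_AB = PD.sum(axis=1) - S_A
    nB = m - nA
    S_BB = T - S_A - 2.0 * S_AB
    E_perm = 2.0 * S_AB / (nA * nB) - S_A / nA**2 - S_BB / nB**2
    p = (1 + int((E_perm >= E_obs - 1e-12).sum())) / (1 + n_permutations)
    return E_obs, p


def holm_sidak_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, returned in input order.

    Sorted ascending, adj_(i) = 1 - (1 - p_(i))^(m - i) for 0-based i,
    enforced monotone non-decreasing and clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


def pca_scores(
    X: np.ndarray, n_pcs: int = 20, seed: int = 0
) -> np.ndarray:
    """Top principal components of the pooled matrix, features standardized."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    n_pcs = min(n_pcs, min(Xs.shape) - 1)
    return PCA(n_components=n_pcs, random_state=seed).fit_transform(Xs)


def screen_perturbations(
    X: np.ndarray,
    labels: np.ndarray,
    control_mask: np.ndarray,
    config: ScreenConfig | None = None,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Energy-distance screen of every perturbation against controls.

    PCA is computed once on the pooled normalized matrix; each
    perturbation's cells are tested against the control cells with the
    permutation energy test, and p-values receive Holm-Sidak family-wise
    correction.  With ``config.equalize_n`` the controls are seeded-
    subsampled to the perturbation's size for each test.
    """
    cfg = config or ScreenConfig()
    labels = np.asarray(labels, dtype=object)
    control_mask = np.asarray(control_mask, dtype=bool)
    if pcs is None:
        pcs = pca_scores(X, cfg.n_pcs, cfg.rng_seed)
    else:
        pcs = np.asarray(pcs, dtype=float)[:, : cfg.n_pcs]
    guides = sorted({g for g, c in zip(labels, control_mask) if g is not None and not c})
    rng = np.random.default_rng(cfg.rng_seed)
    ctrl_idx = np.nonzero(control_mask)[0]
    rows = []
    for g in guides:
        gi = np.nonzero((labels == g) & ~control_mask)[0]
        if len(gi) < 2:
            warnings.warn(f"perturbation {g!r} has <2 cells; skipped", stacklevel=2)
            continue
        ci = ctrl_idx
        if cfg.equalize_n and len(ci) > len(gi):
            ci = rng.choice(ci, size=len(gi), replace=False)
        E, p = energy_permutation_test(
            pcs[gi],
            pcs[ci],
            n_permutations=cfg.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
            method="sampled",
        )
        rows.append({"perturbation": g, "n_cells": len(gi),
                     "energy_distance": E, "raw_p": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["adjusted_p"] = holm_sidak_adjust(res["raw_p"].to_numpy())
        res["significant"] = res["adjusted_p"] < cfg.alpha
    return res.set_index("perturbation") if len(res) else res


# ---------------------------------------------------------------------------
# differential expression

def _mannwhitney_features(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per feature column; constant features -> 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # "auto" gives the exact distribution for small tie-free
            # samples and the tie-corrected normal approximation otherwise
            res = mannwhitneyu(A, B, axis=0, alternative="two-sided",
                               method="auto")
    p = np.asarray(res.pvalue, dtype=float)
    const = (np.ptp(A, axis=0) == 0) & (np.ptp(B, axis=0) == 0) & (
        A[0] == B[0]
    )
    p[const | np.isnan(p)] = 1.0
    return np.clip(p, 0.0, 1.0)


def differential_expression(
    X: np.ndarray,
    group_mask: np.ndarray,
    ctrl_mask: np.ndarray,
    feature_names: list[str] | None = None,
    correction: str = "bh",
    alpha: float = 0.05,
    equalize_n: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney tests of group vs control cells.

    Input is tp10k-log expression.  The log2 fold change compares the
    pseudobulk means of the linearized (expm1) expression with a +1
    pseudocount.  ``correction`` is "bh" (Benjamini-Hochberg) or "by"
    (Benjamini-Yekutieli).  With ``equalize_n`` the larger group is
    seeded-subsampled to the smaller before testing.
    """
    X = np.asarray(X, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    ctrl_mask = np.asarray(ctrl_mask, dtype=bool)
    if group_mask.sum() == 0 or ctrl_mask.sum() == 0:
        raise ValueError("both groups must be non-empty")
    A = X[group_mask]
    B = X[ctrl_mask]
    if equalize_n:
        rng = np.random.default_rng(seed)
        n = min(len(A), len(B))
        if len(A) > n:
            A = A[rng.choice(len(A), n, replace=False)]
        if len(B) > n:
            B = B[rng.choice(len(B), n, replace=False)]
    p = _mannwhitney_features(A, B)
    method = {"bh": "fdr_bh", "by": "fdr_by"}[correction.lower()]
    _, adj, _, _ = multipletests(p, alpha=alpha, method=method)
    lfc = np.log2(np.expm1(A).mean(axis=0) + 1.0) - np.log2(
        np.expm1(B).mean(axis=0) + 1.0
    )
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p": p,
            "adjusted_p": adj,
            "significant": adj < alpha,
        },
        index=pd.Index(
            feature_names if feature_names is not None else range(X.shape[1]),
            name="feature",
        ),
    )


# ---------------------------------------------------------------------------
# gene-set and channel-intensity scores

def _set_scores(
    Z: np.ndarray,
    labels: np.ndarray,
    control_mask: np.ndarray,
    alpha: float,
) -> pd.DataFrame:
    """Mean-z scores per perturbation with Mann-Whitney + BY significance.

    `Z` is the per-cell score (cells,) already reduced over the gene set
    or a single channel.
    """
    labels = np.asarray(labels, dtype=object)
    control_mask = np.asarray(control_mask, dtype=bool)
    ctrl_scores = Z[control_mask]
    guides = sorted({g for g, c in zip(labels, control_mask) if g is not None and not c})
    rows = []
    for g in guides:
        sel = (labels == g) & ~control_mask
        if sel.sum() == 0:
            continue
        s = Z[sel]
        p = float(
            mannwhitneyu(s, ctrl_scores, alternative="two-sided").pvalue
        ) if len(s) else 1.0
        rows.append({"perturbation": g, "score": float(s.mean()),
                     "n_cells": int(sel.sum()), "p": p})
    res = pd.DataFrame(rows)
    if len(res):
        _, adj, _, _ = multipletests(res["p"], alpha=alpha, method="fdr_by")
        res["adjusted_p"] = adj
        res["significant"] = adj < alpha
    return res.set_index("perturbation") if len(res) else res


def geneset_score(
    z_matrix: np.ndarray,
    gene_names: list[str],
    gene_set: list[str],
    labels: np.ndarray,
    control_mask: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean control-relative z over a gene set, per perturbation.

    The per-cell statistic is the mean z across the set's genes; the
    perturbation score is its mean over the perturbation's cells (equal to
    the pseudobulk z change averaged over the set).  Significance compares
    the per-cell distributions to controls by two-sided Mann-Whitney with
    Benjamini-Yekutieli correction across perturbations.
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    name_idx = {g: i for i, g in enumerate(gene_names)}
    idx = [name_idx[g] for g in gene_set if g in name_idx]
    if not idx:
        raise ValueError("no gene-set genes present in the feature names")
    if len(idx) < len(gene_set):
        warnings.warn(
            f"{len(gene_set) - len(idx)} gene-set genes missing; dropped",
            stacklevel=2,
        )
    per_cell = np.asarray(z_matrix, dtype=float)[:, idx].mean(axis=1)
    return _set_scores(per_cell, labels, control_mask, alpha)


def channel_intensity_score(
    z_intensity: np.ndarray,
    channel_names: list[str],
    labels: np.ndarray,
    control_mask: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean control-relative z per morphology channel and perturbation.

    Returns a long table (perturbation, channel) with BY adjustment across
    all perturbation-channel tests.
    """
    Z = np.asarray(z_intensity, dtype=float)
    frames = []
    for j, ch in enumerate(channel_names):
        res = _set_scores(Z[:, j], labels, control_mask, alpha).reset_index()
        res.insert(1, "channel", ch)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    if len(out):
        _, adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_by")
        out["adjusted_p"] = adj
        out["significant"] = adj < alpha
    return out


def pseudobulk_effects_and_correlations(
    X: np.ndarray,
    labels: np.ndarray,
    control_mask: np.ndarray,
    feature_names: list[str],
    top_n: int = 250,
    control_expression: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudobulk effect vectors and their Pearson correlation matrix.

    The effect vector of a perturbation is its pseudobulk mean minus the
    control mean, restricted to the `top_n` genes with the highest control
    expression (``control_expression`` overrides the ranking signal, e.g.
    to rank a z matrix by expression).  Correlations are over the gene
    axis.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    control_mask = np.asarray(control_mask, dtype=bool)
    guides = sorted({g for g, c in zip(labels, control_mask) if g is not None and not c})
    if len(guides) < 2:
        raise ValueError("need at least 2 perturbations for correlations")
    rank_by = (
        np.asarray(control_expression, dtype=float)
        if control_expression is not None
        else X[control_mask].mean(axis=0)
    )
    if top_n > X.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds {X.shape[1]} features; clipped", stacklevel=2
        )
        top_n = X.shape[1]
    top = np.argsort(-rank_by, kind="stable")[:top_n]
    ctrl_mean = X[control_mask][:, top].mean(axis=0)
    effects = {
        g: X[(labels == g) & ~control_mask][:, top].mean(axis=0) - ctrl_mean
        for g in guides
    }
    eff = pd.DataFrame(effects, index=[feature_names[i] for i in top]).T
    corr = pd.DataFrame(
        np.corrcoef(eff.to_numpy()), index=eff.index, columns=eff.index
    )
    return eff, corr


# ---------------------------------------------------------------------------
# label transfer and cluster merging

def knn_label_transfer(
    ref_points: np.ndarray,
    ref_labels: np.ndarray,
    query_points: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """Majority vote over the k nearest reference neighbors.

    Ties are broken by the smaller mean neighbor distance, then by label
    sort order.
    """
    from sklearn.neighbors import NearestNeighbors

    ref_points = np.asarray(ref_points, dtype=float)
    ref_labels = np.asarray(ref_labels, dtype=object)
    if len(ref_points) == 0:
        raise ValueError("empty reference")
    if k > len(ref_points):
        raise ValueError("k exceeds number of reference points")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_points)
    dist, idx = nn.kneighbors(np.asarray(query_points, dtype=float))
    out = np.empty(len(query_points), dtype=object)
    for i in range(len(query_points)):
        lab = ref_labels[idx[i]]
        cands: dict[object, list[float]] = {}
        for l, d in zip(lab, dist[i]):
            cands.setdefault(l, []).append(d)
        best = sorted(
            cands.items(),
            key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), str(kv[0])),
        )[0][0]
        out[i] = best
    return out


def merge_clusters_by_de(
    X: np.ndarray,
    cluster_labels: np.ndarray,
    min_de_genes: int = 10,
    alpha: float = 0.05,
) -> np.ndarray:
    """Greedily merge clusters lacking differential expression.

    Iteratively, any cluster with fewer than `min_de_genes` significantly
    differentially expressed genes (Mann-Whitney + BH at `alpha`, against
    all other cells) is merged into its nearest cluster by centroid
    Euclidean distance, smallest such cluster first, until stable.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(cluster_labels, dtype=object).copy()
    while True:
        uniq = sorted(set(labels), key=str)
        if len(uniq) < 2:
            return labels
        n_de = {}
        sizes = {}
        for c in uniq:
            sel = labels == c
            sizes[c] = int(sel.sum())
            de = differential_expression(X, sel, ~sel, correction="bh", alpha=alpha)
            n_de[c] = int(de["significant"].sum())
        under = [c for c in uniq if n_de[c] < min_de_genes]
        if not under:
            return labels
        c = sorted(under, key=lambda c: (sizes[c], str(c)))[0]
        centroids = {d: X[labels == d].mean(axis=0) for d in uniq}
        others = [d for d in uniq if d != c]
        target = min(
            others,
            key=lambda d: (float(np.linalg.norm(centroids[c] - centroids[d])), str(d)),
        )
        labels[labels == c] = target
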