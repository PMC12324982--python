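"""Molecule-to-cell assignment, duplicate merging, QC and normalization."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pmulti.cells import (
    QcParams,
    assign_molecules_to_cells,
    merge_duplicate_cells,
    normalize_tp10k_log,
    qc_filter,
    regress_out_and_zscore,
)


def _two_cell_mask():
    lab = np.zeros((2, 10, 10), dtype=np.int32)
    lab[:, :, :4] = 1
    lab[:, :, 6:] = 2  # columns 4-5 are background
    return lab


def _mol_table(rng, n, genes=("g1", "g2")):
    return pd.DataFrame(
        {
            "x_um": rng.uniform(0, 10, n),
            "y_um": rng.uniform(0, 10, n),
            "z": rng.integers(0, 2, n),
            "fov": 0,
            "assigned_name": rng.choice(genes, n),
        }
    )


def test_assignment_matches_bruteforce_voxel_lookup(rng):
    lab = _two_cell_mask()
    mols = _mol_table(rng, 100)
    adata = assign_molecules_to_cells(mols, lab, pixel_size_um=1.0)

    expected = {}
    for _, m in mols.iterrows():
        l = lab[int(m.z), int(np.floor(m.y_um)), int(np.floor(m.x_um))]
        if l > 0:
            expected[(f"cell_{l}", m.assigned_name)] = (
                expected.get((f"cell_{l}", m.assigned_name), 0) + 1
            )
    X = adata.X.toarray()
    for (cell, gene), cnt in expected.items():
        i = adata.obs_names.get_loc(cell)
        j = adata.var_names.get_loc(gene)
        assert X[i, j] == cnt
    assert X.sum() == sum(expected.values())


def test_molecule_conservation_accounting(rng):
    lab = _two_cell_mask()
    mols = _mol_table(rng, 60)
    mols.loc[:4, "x_um"] = 55.0  # out of bounds
    adata = assign_molecules_to_cells(mols, lab, pixel_size_um=1.0)
    acc = adata.uns["molecule_assignment"]
    assert acc["n_dropped_out_of_bounds"] == 5
    assert acc["n_assigned"] + acc["n_background"] + acc["n_dropped_out_of_bounds"] == len(mols)
    assert adata.X.sum() == acc["n_assigned"]


def _cells_adata(centroids, fovs, counts, areas=None):
    n = len(centroids)
    obs = pd.DataFrame(
        {
            "fov": fovs,
            "centroid_x_um": [c[0] for c in centroids],
            "centroid_y_um": [c[1] for c in centroids],
            "area_px": areas if areas is not None else np.full(n, 10),
            "z_extent": 1,
        },
        index=pd.Index([f"c{i}" for i in range(n)]),
    )
    X = sp.csr_matrix(np.asarray(counts, dtype=float))
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["g1", "g2"]))
    adata.obs["total_molecules"] = np.asarray(X.sum(axis=1)).ravel()
    return adata


def test_duplicate_cells_merge_and_sum():
    adata = _cells_adata([(0, 0), (0.5, 0)], [0, 1], [[3, 1], [2, 2]], areas=[5, 9])
    out = merge_duplicate_cells(adata, max_centroid_distance_um=5)
    assert out.n_obs == 1
    assert out.X.toarray().tolist() == [[5.0, 3.0]]
    assert out.obs["area_px"].iloc[0] == 9  # metadata from the larger cell


def test_distant_cells_unchanged_and_same_fov_never_merged():
    distant = _cells_adata([(0, 0), (100, 0)], [0, 1], [[1, 0], [0, 1]])
    assert merge_duplicate_cells(distant, 5).n_obs == 2
    same_fov = _cells_adata([(0, 0), (0.5, 0)], [0, 0], [[1, 0], [0, 1]])
    assert merge_duplicate_cells(same_fov, 5).n_obs == 2


def test_chain_merging_is_transitive():
    # A-B within range, B-C within range, A-C far: one connected component
    adata = _cells_adata(
        [(0, 0), (4, 0), (8, 0)], [0, 1, 0], [[1, 0], [1, 0], [1, 0]]
    )
    out = merge_duplicate_cells(adata, max_centroid_distance_um=5)
    assert out.n_obs == 1
    assert out.X.sum() == 3


def test_qc_thresholds_inclusive_and_gene_filter():
    totals = [10, 25, 100, 1500, 1501]
    X = np.zeros((5, 2))
    X[:, 0] = totals
    obs = pd.DataFrame(index=[f"c{i}" for i in range(5)])
    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=pd.DataFrame(index=["g1", "g2"]))
    out = qc_filter(adata, QcParams())
    assert out.n_obs == 3  # 25, 100, 1500 kept (bounds inclusive)
    assert list(out.var_names) == ["g1"]  # g2 detected in no retained cell


def test_qc_matches_naive_oracle_and_is_idempotent(rng):
    X = rng.poisson(8, size=(60, 15)).astype(float)
    X[:5] = 0  # under-count cells
    adata = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(60)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(15)]),
    )
    p = QcParams(min_molecules_per_cell=90, max_molecules_per_cell=140)
    out = qc_filter(adata, p)

    keep = (X.sum(1) >= 90) & (X.sum(1) <= 140)
    sub = X[keep]
    genes = (sub > 0).sum(0) >= 3
    assert out.shape == (int(keep.sum()), int(genes.sum()))
    assert np.array_equal(out.X.toarray(), sub[:, genes])
    twice = qc_filter(out, p)
    assert np.array_equal(twice.X.toarray(), out.X.toarray())


def test_tp10k_log_normalization_arithmetic():
    X = np.array([[1.0, 4.0, 5.0], [5000.0, 4000.0, 1000.0]])
    adata = ad.AnnData(
        X=X.copy(),
        obs=pd.DataFrame(index=["a", "b"]),
        var=pd.DataFrame(index=["g1", "g2", "g3"]),
    )
    out = normalize_tp10k_log(adata)
    got = out.X if isinstance(out.X, np.ndarray) else out.X.toarray()
    assert np.allclose(got[0], np.log1p([1000, 4000, 5000]))
    # rows already summing to 10k unchanged before log
    assert np.allclose(got[1], np.log1p(X[1]))
    # pre-log conservation
    assert np.allclose(np.expm1(got).sum(axis=1), 10_000)


def test_tp10k_rejects_zero_total_cells():
    adata = ad.AnnData(
        X=np.array([[0.0, 0.0]]),
        obs=pd.DataFrame(index=["a"]),
        var=pd.DataFrame(index=["g1", "g2"]),
    )
    with pytest.raises(ValueError, match="zero-total"):
        normalize_tp10k_log(adata)


def _norm_adata(rng, n=200, g=8):
    area = rng.uniform(50, 150, n)
    total = rng.uniform(100, 900, n)
    X = rng.normal(size=(n, g))
    X[:, 0] = 2.0 * area  # feature exactly linear in a covariate
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"area_px": area, "total_molecules": total},
            index=[f"c{i}" for i in range(n)],
        ),
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )
    return adata


def test_regression_removes_covariate_and_standardizes(rng):
    adata = _norm_adata(rng)
    out = regress_out_and_zscore(adata)
    Z = out.X
    # covariate-explained feature collapses to all-zero z-scores
    assert np.allclose(Z[:, 0], 0.0, atol=1e-8)
    assert np.allclose(Z[:, 1:].mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(Z[:, 1:].std(axis=0), 1.0, atol=1e-10)


def test_constant_covariate_dropped_with_warning(rng):
    adata = _norm_adata(rng, n=50)
    adata.obs["area_px"] = 7.0
    with pytest.warns(UserWarning, match="constant"):
        out = regress_out_and_zscore(adata)
    # with the constant covariate dropped, only centering/scaling remains
    assert np.allclose(out.X.mean(axis=0), 0.0, atol=1e-10)
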