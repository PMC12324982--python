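"""From exported molecules to normalized single-cell expression matrices.

Molecules are assigned to segmented cells by looking up the 3D label-image
voxel containing the molecule centroid.  Cells segmented twice in
overlapping fields of view are merged by centroid proximity; cells and
genes are then quality-filtered, counts are normalized to 10,000 per cell
and log1p-transformed, and per-cell technical covariates (area, total
molecule count) are regressed out before z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "QcParams",
    "assign_molecules_to_cells",
    "merge_duplicate_cells",
    "qc_filter",
    "normalize_tp10k_log",
    "regress_out_and_zscore",
]


@dataclass
class QcParams:
    min_molecules_per_cell: int = 25
    max_molecules_per_cell: int = 1500
    min_cells_per_gene: int = 3
    tp_scale: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.min_molecules_per_cell < self.max_molecules_per_cell:
            raise ValueError("need 0 < min < max molecules per cell")
        if self.min_cells_per_gene <= 0 or self.tp_scale <= 0:
            raise ValueError("QC parameters must be positive")


def assign_molecules_to_cells(
    molecules: pd.DataFrame,
    label_image_3d: np.ndarray,
    pixel_size_um: float,
    z_spacing_um: float = 1.5,
    feature_names: list[str] | None = None,
) -> ad.AnnData:
    """Assign molecules to segmented cells by centroid voxel lookup.

    Parameters
    ----------
    molecules : DataFrame
        Exported molecules with ``x_um``, ``y_um``, ``z`` (plane index),
        ``assigned_name`` and optionally ``fov`` columns.
    label_image_3d : ndarray (z, y, x)
        Non-negative integer labels; 0 is background.
    pixel_size_um : float
        Lateral pixel size used to convert micron coordinates to indices.
    z_spacing_um : float
        Plane spacing, recorded as metadata only (``z`` is a plane index).

    Returns
    -------
    AnnData
        cells x features integer counts with per-cell metadata (centroid,
        area, z extent, fov, total molecules) in ``.obs`` and assignment
        accounting in ``.uns['molecule_assignment']``.
    """
    lab = np.asarray(label_image_3d)
    if lab.ndim == 2:
        lab = lab[None, :, :]
    if lab.min() < 0:
        raise ValueError("label image must be non-negative integers")
    nz, ny, nx = lab.shape

    ix = np.floor(molecules["x_um"].to_numpy() / pixel_size_um).astype(np.int64)
    iy = np.floor(molecules["y_um"].to_numpy() / pixel_size_um).astype(np.int64)
    iz = molecules["z"].to_numpy().astype(np.int64)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    n_dropped = int((~inside).sum())

    labels = np.zeros(len(molecules), dtype=np.int64)
    labels[inside] = lab[iz[inside], iy[inside], ix[inside]]
    assigned = labels > 0

    cell_ids = np.unique(lab)
    cell_ids = cell_ids[cell_ids > 0]
    if feature_names is None:
        feature_names = sorted(molecules["assigned_name"].dropna().unique())
    feat_idx = {f: j for j, f in enumerate(feature_names)}
    cell_idx = {c: i for i, c in enumerate(cell_ids)}

    keep = assigned & molecules["assigned_name"].isin(feature_names).to_numpy()
    rows = np.array([cell_idx[c] for c in labels[keep]], dtype=np.int64)
    cols = molecules.loc[keep, "assigned_name"].map(feat_idx).to_numpy(np.int64)
    X = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(cell_ids), len(feature_names)),
    ).tocsr()

    # per-cell geometry from the mask
    flat = lab.ravel()
    vox_per_cell = np.bincount(flat, minlength=int(lab.max()) + 1)
    z_extent = np.zeros(int(lab.max()) + 1, dtype=np.int64)
    area = np.zeros(int(lab.max()) + 1, dtype=np.int64)
    for z in range(nz):
        plane_counts = np.bincount(lab[z].ravel(), minlength=int(lab.max()) + 1)
        z_extent += plane_counts > 0
        area = np.maximum(area, plane_counts)
    # centroids in microns
    zz, yy, xx = np.nonzero(lab)
    lab_nz = lab[zz, yy, xx]
    cx = np.bincount(lab_nz, weights=xx, minlength=int(lab.max()) + 1)
    cy = np.bincount(lab_nz, weights=yy, minlength=int(lab.max()) + 1)
    with np.errstate(invalid="ignore"):
        cx = (cx / np.maximum(vox_per_cell, 1) + 0.5) * pixel_size_um
        cy = (cy / np.maximum(vox_per_cell, 1) + 0.5) * pixel_size_um

    if "fov" in molecules.columns:
        fov_mode = (
            molecules.loc[assigned]
            .groupby(labels[assigned])["fov"]
            .agg(lambda s: s.mode().iloc[0])
        )
        fovs = np.array([fov_mode.get(c, -1) for c in cell_ids])
    else:
        fovs = np.full(len(cell_ids), -1)

    obs = pd.DataFrame(
        {
            "fov": fovs,
            "centroid_x_um": cx[cell_ids],
            "centroid_y_um": cy[cell_ids],
            "area_px": area[cell_ids],
            "z_extent": z_extent[cell_ids],
        },
        index=pd.Index([f"cell_{c}" for c in cell_ids], name="cell_id"),
    )
    adata = ad.AnnData(
        X=X,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(feature_names, name="feature")),
    )
    adata.obs["total_molecules"] = np.asarray(adata.X.sum(axis=1)).ravel()
    adata.uns["molecule_assignment"] = {
        "n_input": len(molecules),
        "n_assigned": int(keep.sum()),
        "n_background": int((assigned & ~keep).sum() + (inside & ~assigned).sum()),
        "n_dropped_out_of_bounds": n_dropped,
        "pixel_size_um": pixel_size_um,
        "z_spacing_um": z_spacing_um,
    }
    return adata


def merge_duplicate_cells(
    adata: ad.AnnData, max_centroid_distance_um: float = 5.0
) -> ad.AnnData:
    """Merge cells re-segmented in multiple fields of view.

    Cells from *different* FOVs whose centroids lie within
    ``max_centroid_distance_um`` are unified transitively (connected
    components).  Counts are summed; metadata comes from the largest-area
    member of each component.
    """
    xy = adata.obs[["centroid_x_um", "centroid_y_um"]].to_numpy()
    fov = adata.obs["fov"].to_numpy()
    tree = cKDTree(xy)
    pairs = tree.query_pairs(max_centroid_distance_um, output_type="ndarray")
    if len(pairs):
        pairs = pairs[fov[pairs[:, 0]] != fov[pairs[:, 1]]]
    n = adata.n_obs
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1]) if len(pairs) else ([], [])),
        shape=(n, n),
    )
    n_comp, comp = connected_components(graph, directed=False)
    areas = adata.obs["area_px"].to_numpy()
    rep = np.zeros(n_comp, dtype=np.int64)
    for c in range(n_comp):
        members = np.nonzero(comp == c)[0]
        rep[c] = members[np.argmax(areas[members])]
    M = sp.coo_matrix(
        (np.ones(n), (comp, np.arange(n))), shape=(n_comp, n)
    ).tocsr()
    X = M @ sp.csr_matrix(adata.X)
    obs = adata.obs.iloc[rep].copy()
    obs["total_molecules"] = np.asarray(X.sum(axis=1)).ravel()
    out = ad.AnnData(X=X.tocsr(), obs=obs, var=adata.var.copy(), uns=dict(adata.uns))
    out.uns["n_merged_duplicates"] = int(n - n_comp)
    return out


def qc_filter(adata: ad.AnnData, params: QcParams | None = None) -> ad.AnnData:
    """Cell then gene quality filter.

    Keeps cells with min <= total molecules <= max (bounds inclusive: the
    removal rule is "less than min or greater than max"), then drops genes
    detected in fewer than ``min_cells_per_gene`` of the remaining cells.
    """
    p = params or QcParams()
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    keep_cells = (totals >= p.min_molecules_per_cell) & (
        totals <= p.max_molecules_per_cell
    )
    sub = adata[keep_cells].copy()
    detected = np.asarray((sub.X > 0).sum(axis=0)).ravel()
    keep_genes = detected >= p.min_cells_per_gene
    out = sub[:, keep_genes].copy()
    out.obs["total_molecules"] = np.asarray(out.X.sum(axis=1)).ravel()
    if out.n_obs == 0 or out.n_vars == 0:
        warnings.warn("QC filter produced an empty matrix", stacklevel=2)
    return out


def normalize_tp10k_log(adata: ad.AnnData, tp_scale: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to `tp_scale` total counts, then log1p."""
    import scanpy as sc

    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; run qc_filter first")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=tp_scale)
    sc.pp.log1p(out)
    return out


def regress_out_and_zscore(
    adata: ad.AnnData,
    covariates: tuple[str, ...] = ("area_px", "total_molecules"),
) -> ad.AnnData:
    """OLS-remove per-cell covariates from each feature, then z-score.

    A single least-squares solve with an intercept handles all features at
    once; residuals are standardized per feature (mean 0, sd 1).  Constant
    covariates are dropped with a warning; zero-variance residual features
    get z-score 0.
    """
    Y = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X, float)
    cols = [np.ones(adata.n_obs)]
    for c in covariates:
        v = adata.obs[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(v)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    mu = resid.mean(axis=0)
    sd = resid.std(axis=0)
    # features fully explained by the covariates leave only round-off
    # residuals; their z-scores are defined as 0 rather than amplified noise
    nz = sd > 1e-8 * np.maximum(Y.std(axis=0), 1e-300)
    z = np.zeros_like(resid)
    z[:, nz] = (resid[:, nz] - mu[nz]) / sd[nz]
    out = adata.copy()
    out.X = z
    return out
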