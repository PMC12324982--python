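"""Readers and writers for the pipeline's plain-text interchange formats.

Codebooks and molecule tables travel as CSV, count matrices as
MatrixMarket (.mtx) with row/column TSVs plus a metadata CSV, label
images as multi-page TIFF, configuration as YAML and run manifests as
JSON.  All round-trips are lossless: integers bit-exact, floats at full
repr precision.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .codebook import Codebook

__all__ = [
    "ParseError",
    "read_codebook", "write_codebook",
    "read_molecules", "write_molecules",
    "read_matrix", "write_matrix",
    "read_labels", "write_labels",
    "read_yaml", "write_yaml",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# -- codebook ---------------------------------------------------------------

def write_codebook(codebook: Codebook, path: str | Path) -> None:
    codebook.to_frame().to_csv(path, index=False)


def read_codebook(
    path: str | Path, weight: int | None = None, min_distance: int | None = None
) -> Codebook:
    df = pd.read_csv(path)
    required = {"name", "is_blank"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: line 1: header must contain {sorted(required)} "
            f"and bit_* columns, got {list(df.columns)[:5]}"
        )
    bit_cols = [c for c in df.columns if c.startswith("bit_")]
    bit_cols.sort(key=lambda c: int(c.split("_")[1]))
    bits = df[bit_cols].to_numpy()
    if not np.isin(bits, (0, 1)).all():
        bad = np.nonzero(~np.isin(bits, (0, 1)).all(axis=1))[0][0]
        raise ParseError(f"{path}: line {bad + 2}: non-binary bit value")
    weights = bits.sum(axis=1)
    w = weight if weight is not None else int(np.bincount(weights).argmax())
    return Codebook(
        n_bits=len(bit_cols),
        weight=w,
        min_distance=min_distance if min_distance is not None else 0,
        names=df["name"].astype(str).tolist(),
        bits=bits.astype(np.uint8),
        is_blank=df["is_blank"].to_numpy().astype(bool),
    )


# -- molecule tables --------------------------------------------------------

def write_molecules(molecules: pd.DataFrame, path: str | Path) -> None:
    # default float formatting is repr-shortest, which round-trips exactly
    molecules.to_csv(path, index=False)


def read_molecules(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_um", "y_um", "z"):
        if col not in df.columns:
            raise ParseError(f"{path}: line 1: missing required column {col!r}")
    return df


# -- count matrices (MTX + TSVs + metadata CSV) -----------------------------

def write_matrix(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write AnnData as <prefix>.mtx / .cells.tsv / .features.tsv / .obs.csv."""
    prefix = Path(prefix)
    X = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(str(prefix) + ".mtx", X)
    pd.Series(adata.obs_names).to_csv(
        f"{prefix}.cells.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        f"{prefix}.features.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(f"{prefix}.obs.csv")


def _validate_mtx(path: Path) -> None:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("%%MatrixMarket"):
            raise ParseError(f"{path}: line 1: not a MatrixMarket file")
        lineno = 1
        line = "%"
        while line.startswith("%"):
            line = fh.readline()
            lineno += 1
        try:
            nr, nc, nnz = (int(t) for t in line.split())
        except ValueError as e:
            raise ParseError(f"{path}: line {lineno}: bad size header") from e
        for i, entry in enumerate(fh, start=lineno + 1):
            parts = entry.split()
            if not parts:
                continue
            r, c = int(parts[0]), int(parts[1])
            if not (1 <= r <= nr and 1 <= c <= nc):
                raise ParseError(
                    f"{path}: line {i}: entry ({r}, {c}) outside declared "
                    f"dimensions {nr} x {nc}"
                )


def read_matrix(prefix: str | Path) -> ad.AnnData:
    prefix = Path(prefix)
    mtx = Path(f"{prefix}.mtx")
    _validate_mtx(mtx)
    X = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    cells = pd.read_csv(f"{prefix}.cells.tsv", sep="\t", header=None)[0].astype(str)
    feats = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None)[0].astype(str)
    if X.shape != (len(cells), len(feats)):
        raise ParseError(
            f"{mtx}: line 2: declared shape {X.shape} does not match "
            f"{len(cells)} cells x {len(feats)} features"
        )
    if len(set(cells)) != len(cells) or len(set(feats)) != len(feats):
        raise ParseError(f"{prefix}: duplicate cell or feature labels")
    obs_path = Path(f"{prefix}.obs.csv")
    obs = (
        pd.read_csv(obs_path, index_col=0)
        if obs_path.exists()
        else pd.DataFrame(index=cells)
    )
    obs.index = obs.index.astype(str)
    adata = ad.AnnData(
        X=X, obs=obs.loc[cells], var=pd.DataFrame(index=pd.Index(feats, name="feature"))
    )
    return adata


# -- label images -----------------------------------------------------------

def write_labels(labels: np.ndarray, path: str | Path) -> None:
    import tifffile

    # one grayscale page per z-plane (never RGB interpretation of z=3/4)
    tifffile.imwrite(path, np.asarray(labels), photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    import tifffile

    lab = tifffile.imread(path)
    if not np.issubdtype(lab.dtype, np.integer):
        raise ParseError(f"{path}: label image must be integer-typed")
    return lab


# -- config / manifest ------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, seeds: dict) -> Path:
    """JSON manifest with versions, seeds and output hashes for re-runs."""
    import pmulti

    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "pmulti_version": pmulti.__version__,
        "numpy_version": np.__version__,
        "config": config,
        "seeds": seeds,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
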