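"""Perturbation identity calling from imaging barcodes and sgRNA UMIs.

Both readouts produce a per-cell table of candidate guides with evidence
counts; a cell is retained for analysis only when exactly one guide is
called (multiply infected or ambiguous cells are excluded).  At low
multiplicity of infection, integrations per cell are Poisson distributed,
which fixes the expected fraction of single-perturbation cells among
transduced cells.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "call_imaging_barcodes",
    "call_sequencing_guides",
    "default_guide_thresholds",
    "poisson_single_fraction",
    "moi_from_single_fraction",
]


def _call_table(counts: pd.DataFrame, called: np.ndarray) -> pd.DataFrame:
    guides = counts.columns.to_numpy()
    rows = []
    for i, cell in enumerate(counts.index):
        sel = np.nonzero(called[i])[0]
        rows.append(
            {
                "cell_id": cell,
                "called_guides": list(guides[sel]),
                "evidence": [int(counts.iat[i, j]) for j in sel],
                "n_called": len(sel),
            }
        )
    out = pd.DataFrame(rows).set_index("cell_id")
    out["is_single"] = out["n_called"] == 1
    out["retained"] = out["is_single"]
    out["guide"] = [g[0] if len(g) == 1 else None for g in out["called_guides"]]
    return out


def call_imaging_barcodes(
    barcode_counts: pd.DataFrame, min_molecules: int = 3
) -> pd.DataFrame:
    """Call guides from imaging barcode molecule counts per cell.

    A guide is called when its count is strictly greater than
    ``min_molecules`` (default: > 3 molecules).  Cells partition into
    0 / 1 / >=2 call classes; only single-call cells are retained.
    """
    called = barcode_counts.to_numpy() > min_molecules
    return _call_table(barcode_counts, called)


def default_guide_thresholds(
    umi_counts: pd.DataFrame, floor: int = 5, ambient_multiplier: float = 10.0
) -> dict[str, float]:
    """Heuristic per-guide UMI thresholds.

    For each guide: ``max(floor, ambient_multiplier x median ambient UMI)``
    where the ambient level is the guide's median UMI count across cells
    whose top guide is a different one.  This stands in for empirically
    tuned thresholds (real screens tune them against on-target knockdown),
    and is documented as such.
    """
    M = umi_counts.to_numpy(dtype=float)
    top = np.argmax(M, axis=1)
    thresholds = {}
    for j, g in enumerate(umi_counts.columns):
        others = M[top != j, j]
        ambient = float(np.median(others)) if len(others) else 0.0
        thresholds[g] = max(float(floor), ambient_multiplier * ambient)
    return thresholds


def call_sequencing_guides(
    umi_counts: pd.DataFrame,
    per_guide_thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Call guides from sequencing UMI counts with per-guide thresholds.

    A guide is called when its UMI count is >= its threshold; cells with
    exactly one called guide are retained, all others excluded.  Guides
    missing a threshold fall back to the default heuristic with a warning.
    """
    if umi_counts.shape[1] == 0:
        raise ValueError("guide UMI matrix has no guide columns")
    if per_guide_thresholds is None:
        per_guide_thresholds = default_guide_thresholds(umi_counts)
    else:
        missing = [g for g in umi_counts.columns if g not in per_guide_thresholds]
        if missing:
            warnings.warn(
                f"{len(missing)} guides missing thresholds; using default "
                f"heuristic for {missing[:3]}...",
                stacklevel=2,
            )
            fallback = default_guide_thresholds(umi_counts)
            per_guide_thresholds = {**{g: fallback[g] for g in missing},
                                    **per_guide_thresholds}
    thr = np.array([per_guide_thresholds[g] for g in umi_counts.columns])
    called = umi_counts.to_numpy(dtype=float) >= thr[None, :]
    return _call_table(umi_counts, called)


def poisson_single_fraction(lam: float) -> float:
    """P(exactly one integration | at least one) under Poisson(lambda).

    Equals lambda * exp(-lambda) / (1 - exp(-lambda)).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return lam * math.exp(-lam) / (1.0 - math.exp(-lam))


def moi_from_single_fraction(single_fraction: float) -> float:
    """Invert :func:`poisson_single_fraction` for an observed fraction."""
    if not 0 < single_fraction < 1:
        raise ValueError("single fraction must be in (0, 1)")
    return float(
        brentq(lambda lam: poisson_single_fraction(lam) - single_fraction, 1e-9, 50.0)
    )
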