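"""Constant-weight, minimum-distance codebooks for combinatorial FISH readout.

Each RNA species (or perturbation barcode) is identified by a binary codeword
read out over sequential hybridization rounds.  Codewords share a fixed
Hamming weight (number of "on" bits) and a guaranteed minimum pairwise
Hamming distance; distance >= 4 permits correction of any single-bit readout
error.  Codewords left unassigned to a target are "blanks" — valid codewords
that should never be detected, whose observed frequency estimates the
molecular misidentification rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "CodebookReport",
    "CodebookShortfallError",
    "generate_constant_weight_code",
    "assign_codewords",
    "verify_codebook",
]


class CodebookShortfallError(ValueError):
    """Greedy construction produced fewer codewords than required.

    Carries the partial codebook in ``.codebook`` and the achieved count in
    ``.achieved`` so the caller can inspect the shortfall.
    """

    def __init__(self, achieved: int, required: int, codebook: "Codebook"):
        self.achieved = achieved
        self.required = required
        self.codebook = codebook
        super().__init__(
            f"greedy construction reached {achieved} codewords, "
            f"{required} required"
        )


@dataclass
class Codebook:
    """A named constant-weight code.

    Attributes
    ----------
    n_bits : int
        Codeword length (number of readout bits).
    weight : int
        Hamming weight of every codeword.
    min_distance : int
        Guaranteed minimum pairwise Hamming distance.
    names : list of str
        One unique name per codeword (gene, barcode, or ``Blank-*``).
    bits : ndarray of uint8, shape (n_codewords, n_bits)
        The codeword matrix.
    is_blank : ndarray of bool
        True for codewords not assigned to any target.
    """

    n_bits: int
    weight: int
    min_distance: int
    names: list[str]
    bits: np.ndarray
    is_blank: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != self.n_bits:
            raise ValueError("bits must be (n_codewords, n_bits)")
        if len(self.names) != self.bits.shape[0]:
            raise ValueError("names and bits length mismatch")
        if self.is_blank is None:
            self.is_blank = np.zeros(len(self.names), dtype=bool)
        self.is_blank = np.asarray(self.is_blank, dtype=bool)

    def __len__(self) -> int:
        return self.bits.shape[0]

    @property
    def n_blanks(self) -> int:
        return int(self.is_blank.sum())

    @property
    def coding_names(self) -> list[str]:
        return [n for n, b in zip(self.names, self.is_blank) if not b]

    @property
    def blank_names(self) -> list[str]:
        return [n for n, b in zip(self.names, self.is_blank) if b]

    def codeword(self, name: str) -> np.ndarray:
        return self.bits[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.bits, columns=[f"bit_{i}" for i in range(self.n_bits)]
        )
        df.insert(0, "is_blank", self.is_blank.astype(int))
        df.insert(0, "name", self.names)
        return df


@dataclass
class CodebookReport:
    """Exhaustive validity report for a codebook."""

    min_pairwise_distance: int
    weight_violations: list[str]
    duplicate_names: list[str]
    duplicate_codewords: int
    n_blanks: int

    @property
    def ok(self) -> bool:
        return (
            not self.weight_violations
            and not self.duplicate_names
            and self.duplicate_codewords == 0
        )


def _candidate_matrix(n_bits: int, weight: int) -> np.ndarray:
    """All weight-`weight` vectors of length `n_bits` in lexicographic order.

    Order is lexicographic over the sorted tuples of on-bit positions, i.e.
    the order produced by ``itertools.combinations(range(n_bits), weight)``.
    """
    combos = list(itertools.combinations(range(n_bits), weight))
    cands = np.zeros((len(combos), n_bits), dtype=np.uint8)
    for i, pos in enumerate(combos):
        cands[i, list(pos)] = 1
    return cands


def generate_constant_weight_code(
    n_bits: int,
    weight: int,
    min_distance: int,
    n_required: int = 1,
    candidate_order: str | np.ndarray = "lexicographic",
) -> Codebook:
    """Greedy lexicode construction of a constant-weight code.

    Scans candidate weight-`weight` vectors in a fixed order and accepts a
    candidate iff its Hamming distance to every previously accepted codeword
    is at least `min_distance`.  The result is deterministic given the
    candidate order and always valid; all accepted codewords are returned
    (possibly more than `n_required`), named ``cw_0000`` onward, all
    initially marked blank until :func:`assign_codewords` assigns targets.

    Parameters
    ----------
    candidate_order : "lexicographic" or ndarray
        Either the default lexicographic enumeration or an explicit
        (n_candidates, n_bits) 0/1 array scanned in row order.

    Raises
    ------
    ValueError
        Infeasible parameters (weight > n_bits, odd min_distance, ...).
    CodebookShortfallError
        Fewer than `n_required` codewords achievable by the greedy pass;
        the partial codebook is attached to the exception.
    """
    if not 0 < weight <= n_bits:
        raise ValueError(f"need 0 < weight <= n_bits, got {weight}/{n_bits}")
    if min_distance % 2 != 0 or min_distance < 0:
        # distances between equal-weight vectors are even
        raise ValueError("min_distance must be a non-negative even integer")
    if n_required < 1:
        raise ValueError("n_required must be >= 1")

    if isinstance(candidate_order, str):
        if candidate_order != "lexicographic":
            raise ValueError(f"unknown candidate order {candidate_order!r}")
        cands = _candidate_matrix(n_bits, weight)
    else:
        cands = np.asarray(candidate_order, dtype=np.uint8)
        if cands.ndim != 2 or cands.shape[1] != n_bits:
            raise ValueError("candidate_order array must be (m, n_bits)")
        if not ((cands.sum(axis=1) == weight).all()):
            raise ValueError("candidate_order rows must all have the target weight")

    accepted = np.empty((cands.shape[0], n_bits), dtype=np.uint8)
    n_acc = 0
    for v in cands:
        if n_acc:
            d = np.bitwise_xor(accepted[:n_acc], v).sum(axis=1)
            if (d < min_distance).any():
                continue
        accepted[n_acc] = v
        n_acc += 1
    bits = accepted[:n_acc].copy()
    names = [f"cw_{i:04d}" for i in range(n_acc)]
    book = Codebook(
        n_bits=n_bits,
        weight=weight,
        min_distance=min_distance,
        names=names,
        bits=bits,
        is_blank=np.ones(n_acc, dtype=bool),
    )
    if n_acc < n_required:
        raise CodebookShortfallError(n_acc, n_required, book)
    return book


def assign_codewords(
    target_names: list[str], codebook: Codebook, seed: int
) -> Codebook:
    """Randomly assign targets to codewords; the remainder become blanks.

    Each target receives one distinct codeword chosen by a seeded uniform
    random permutation of the codebook.  Unassigned codewords are renamed
    ``Blank-01`` onward and flagged ``is_blank``.
    """
    n_targets = len(target_names)
    if len(set(target_names)) != n_targets:
        raise ValueError("target names must be unique")
    if n_targets > len(codebook):
        raise ValueError(
            f"{n_targets} targets exceed codebook capacity {len(codebook)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(codebook))
    names = [""] * len(codebook)
    is_blank = np.ones(len(codebook), dtype=bool)
    for t, idx in zip(target_names, perm[:n_targets]):
        names[idx] = t
        is_blank[idx] = False
    blank_i = 0
    for i in range(len(codebook)):
        if is_blank[i]:
            blank_i += 1
            names[i] = f"Blank-{blank_i:02d}"
    return Codebook(
        n_bits=codebook.n_bits,
        weight=codebook.weight,
        min_distance=codebook.min_distance,
        names=names,
        bits=codebook.bits.copy(),
        is_blank=is_blank,
    )


def verify_codebook(codebook: Codebook) -> CodebookReport:
    """Exhaustive pairwise verification of the codebook invariants."""
    if len(codebook) == 0:
        raise ValueError("empty codebook")
    bits = codebook.bits.astype(np.int16)
    weights = bits.sum(axis=1)
    weight_violations = [
        codebook.names[i]
        for i in np.nonzero(weights != codebook.weight)[0]
    ]
    seen: dict[str, int] = {}
    duplicate_names = []
    for n in codebook.names:
        seen[n] = seen.get(n, 0) + 1
    duplicate_names = [n for n, c in seen.items() if c > 1]

    n = len(codebook)
    if n > 1:
        # pairwise Hamming distances via the inner-product identity
        gram = bits @ bits.T
        d = weights[:, None] + weights[None, :] - 2 * gram
        iu = np.triu_indices(n, k=1)
        pair_d = d[iu]
        min_d = int(pair_d.min())
        duplicate_codewords = int((pair_d == 0).sum())
    else:
        min_d = codebook.n_bits  # vacuous
        duplicate_codewords = 0
    return CodebookReport(
        min_pairwise_distance=min_d,
        weight_violations=weight_violations,
        duplicate_names=duplicate_names,
        duplicate_codewords=duplicate_codewords,
        n_blanks=codebook.n_blanks,
    )
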