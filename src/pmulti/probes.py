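"""Padlock encoding-probe window selection on target cDNA sequences.

A padlock probe is a single oligo whose two arms hybridize head-to-tail on
the target; after ligation it is circularized and amplified by rolling
circle amplification.  Probe design scans the target for 60-nt windows that
split into two 30-nt halves, each satisfying GC-content and melting-
temperature bounds, with optional specificity and contaminant-homology
screens, and rejects windows whose ligation junction would place a G or C
at the donor (5'-phosphorylated) end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "ProbeDesignParams",
    "ProbeWindow",
    "design_padlock_windows",
    "gc_fraction",
    "melting_temperature",
    "assemble_encoding_probe",
]

_VALID = set("ACGT")


@dataclass
class ProbeDesignParams:
    """Thresholds for padlock probe-window acceptance.

    Defaults follow standard combinatorial-FISH probe design practice:
    60-nt windows split into 30-nt halves, 30-70% GC, Tm 60-80 C,
    isoform/gene specificity indices >= 0.7/0.75, no contaminant homology
    longer than 15 nt, and no G/C at the donor ligation junction.
    """

    window_length: int = 60
    half_length: int = 30
    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 60.0
    tm_max: float = 80.0
    isoform_spec_min: float = 0.7
    gene_spec_min: float = 0.75
    max_rrna_trna_homology: int = 15
    probes_per_target: int = 8
    forbidden_donor_bases: frozenset = frozenset({"G", "C"})
    # Tm model conditions (nearest-neighbor thermodynamics)
    na_mM: float = 300.0
    probe_nM: float = 5.0
    spec_kmer: int = 17

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if not self.tm_min < self.tm_max:
            raise ValueError("tm_min must be < tm_max")
        if self.window_length != 2 * self.half_length:
            raise ValueError("window_length must equal 2 * half_length")


@dataclass
class ProbeWindow:
    target_name: str
    start: int
    left_half: str
    right_half: str
    gc_left: float
    gc_right: float
    tm_left: float
    tm_right: float
    donor_base: str
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    selected: bool = False

    @property
    def sequence(self) -> str:
        return self.left_half + self.right_half


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, params: ProbeDesignParams | None = None) -> float:
    """Nearest-neighbor Tm (degrees C) at the configured salt/probe conc."""
    p = params or ProbeDesignParams()
    return float(
        _mt.Tm_NN(seq, Na=p.na_mM, dnac1=p.probe_nM, dnac2=0, saltcorr=5)
    )


def _kmers(seq: str, k: int):
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _build_kmer_index(reference: dict[str, str], k: int) -> dict[str, set]:
    index: dict[str, set] = {}
    for name, seq in reference.items():
        for km in _kmers(seq.upper(), k):
            index.setdefault(km, set()).add(name)
    return index


def design_padlock_windows(
    target_sequence: str,
    params: ProbeDesignParams | None = None,
    target_name: str = "target",
    reference: dict[str, str] | None = None,
    isoform_to_gene: dict[str, str] | None = None,
    contaminants: dict[str, str] | None = None,
    probes_per_target: int | None = None,
) -> list[ProbeWindow]:
    """Scan every window start and select non-overlapping accepted windows.

    Every start position yields a :class:`ProbeWindow` carrying per-rule
    pass/fail; up to ``probes_per_target`` accepted windows are then
    selected greedily 5'->3' without overlap (``selected`` flag).

    The specificity indices are the fraction of the window's k-mers unique
    to this target's isoform (resp. gene, via ``isoform_to_gene``) within
    ``reference``; both auto-pass when no reference is supplied.  The
    contaminant screen rejects windows sharing a substring longer than
    ``max_rrna_trna_homology`` nt with any sequence in ``contaminants``;
    it auto-passes when absent.
    """
    p = params or ProbeDesignParams()
    n_select = p.probes_per_target if probes_per_target is None else probes_per_target
    seq = target_sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT characters in target sequence: {sorted(bad)}")
    L, H = p.window_length, p.half_length
    if len(seq) < L:
        warnings.warn(
            f"target shorter than window length ({len(seq)} < {L}); no windows",
            stacklevel=2,
        )
        return []

    ref_index = (
        _build_kmer_index(reference, p.spec_kmer) if reference else None
    )
    contam_k = p.max_rrna_trna_homology + 1
    contam_index = (
        set().union(*(_kmers(s.upper(), contam_k) for s in contaminants.values()))
        if contaminants
        else None
    )

    windows: list[ProbeWindow] = []
    for start in range(len(seq) - L + 1):
        left = seq[start : start + H]
        right = seq[start + H : start + L]
        reasons: list[str] = []
        gcs = (gc_fraction(left), gc_fraction(right))
        if not all(p.gc_min <= g <= p.gc_max for g in gcs):
            reasons.append("gc_out_of_range")
        tms = (melting_temperature(left, p), melting_temperature(right, p))
        if not all(p.tm_min <= t <= p.tm_max for t in tms):
            reasons.append("tm_out_of_range")
        donor = right[0]
        if donor in p.forbidden_donor_bases:
            reasons.append("donor_junction")
        if contam_index is not None:
            win = left + right
            if any(km in contam_index for km in _kmers(win, contam_k)):
                reasons.append("contaminant_homology")
        if ref_index is not None:
            win_kmers = [
                seq[start + i : start + i + p.spec_kmer]
                for i in range(L - p.spec_kmer + 1)
            ]
            iso_hits = [ref_index.get(km, {target_name}) for km in win_kmers]
            iso_spec = sum(1 for h in iso_hits if h <= {target_name}) / len(iso_hits)
            if iso_spec < p.isoform_spec_min:
                reasons.append("isoform_specificity")
            if isoform_to_gene is not None:
                gene = isoform_to_gene.get(target_name, target_name)
                gene_spec = sum(
                    1
                    for h in iso_hits
                    if all(isoform_to_gene.get(x, x) == gene for x in h)
                ) / len(iso_hits)
                if gene_spec < p.gene_spec_min:
                    reasons.append("gene_specificity")
        windows.append(
            ProbeWindow(
                target_name=target_name,
                start=start,
                left_half=left,
                right_half=right,
                gc_left=gcs[0],
                gc_right=gcs[1],
                tm_left=tms[0],
                tm_right=tms[1],
                donor_base=donor,
                accepted=not reasons,
                rejection_reasons=reasons,
            )
        )

    # greedy 5'->3' non-overlapping selection
    next_free = 0
    n_sel = 0
    for w in windows:
        if n_sel >= n_select:
            break
        if w.accepted and w.start >= next_free:
            w.selected = True
            next_free = w.start + L
            n_sel += 1
    return windows


_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def assemble_encoding_probe(
    window: ProbeWindow,
    readout_sequences: list[str],
    rca_primer: str,
    left_handle: str = "",
    right_handle: str = "",
) -> str:
    """Concatenate a full encoding-probe sequence for one window.

    The probe arms are the reverse complements of the two target halves;
    between them sit the RCA primer-binding sequence and the reverse
    complements of the readout sequences that encode the codeword's on
    bits.  PCR handles are appended outside the arms.  Plain sequence
    assembly only; no chemistry is modeled.
    """
    readouts = "".join(reverse_complement(r) for r in readout_sequences)
    return (
        left_handle
        + reverse_complement(window.right_half)
        + rca_primer
        + readouts
        + reverse_complement(window.left_half)
        + right_handle
    )
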