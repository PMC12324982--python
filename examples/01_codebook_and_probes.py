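"""Design an error-robust codebook and padlock probe windows.

Builds the two codebooks used for imaging (21-bit weight-4 for endogenous
genes, 18-bit weight-6 for perturbation barcodes), assigns targets to
codewords, and scans a toy transcript for acceptable padlock windows.
"""

import numpy as np

from pmulti import (
    ProbeDesignParams,
    assign_codewords,
    design_padlock_windows,
    generate_constant_weight_code,
    verify_codebook,
)

# --- codebooks -------------------------------------------------------------
gene_book = generate_constant_weight_code(21, 4, 4, n_required=205)
barcode_book = generate_constant_weight_code(18, 6, 4, n_required=456)
for label, book in [("genes 21/4/4", gene_book), ("barcodes 18/6/4", barcode_book)]:
    rep = verify_codebook(book)
    print(f"{label}: {len(book)} codewords, min pairwise distance "
          f"{rep.min_pairwise_distance}")
# distance >= 4 means any single readout error is uniquely correctable.

assigned = assign_codewords([f"gene_{i:03d}" for i in range(205)], gene_book, seed=0)
print(f"assigned 205 genes; {assigned.n_blanks} blanks remain "
      "(blank detections estimate the misidentification rate)")

# --- probe windows ---------------------------------------------------------
rng = np.random.default_rng(0)
transcript = "".join(rng.choice(list("ACGT"), size=400, p=[0.3, 0.2, 0.2, 0.3]))
windows = design_padlock_windows(transcript, ProbeDesignParams(), probes_per_target=8)
accepted = [w for w in windows if w.accepted]
selected = [w for w in windows if w.selected]
print(f"{len(windows)} windows scanned, {len(accepted)} pass GC/Tm/junction "
      f"rules, {len(selected)} non-overlapping probes selected")
for w in selected[:3]:
    print(f"  start={w.start:3d} GC=({w.gc_left:.2f},{w.gc_right:.2f}) "
          f"Tm=({w.tm_left:.1f},{w.tm_right:.1f}) donor={w.donor_base}")
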