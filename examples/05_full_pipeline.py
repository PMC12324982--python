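"""Run the whole pipeline end to end on a small simulated screen.

simulate -> decode -> filter -> assign to cells -> QC -> normalize ->
call guides -> energy screen -> zonation, with every intermediate written
to plain-text formats plus a reproducibility manifest.
"""

import json

from pmulti import GuideEffect, ScreenConfig, TissueSimConfig
from pmulti.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    sim=TissueSimConfig(
        n_cells=400,
        n_genes=60,
        field_size_um=500,
        vein_spacing_um=160,
        mean_counts_per_cell=400,
        guides={
            "ctrl_0": GuideEffect(),
            "ctrl_1": GuideEffect(),
            "hit": GuideEffect(gene_shifts={f"Gene_{i:03d}": 1.5 for i in range(8)}),
        },
        lambda_moi=1.0,  # inflated so the tiny demo has enough perturbed cells
        rng_seed=0,
    ),
    screen=ScreenConfig(n_permutations=500, rng_seed=0),
    seed=0,
)

summary = run_pipeline(config, "scratch/pipeline_demo")
print(json.dumps(summary, indent=2, default=str))
print("\nkey numbers: decode.blank_fraction is the misidentification rate "
      "after the adaptive filter (target <= 0.05); screen.n_significant "
      "counts guides with Holm-Sidak-corrected energy-test p < 0.05.")
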