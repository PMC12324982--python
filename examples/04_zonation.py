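"""Zonation scoring and zone segmentation: re-zonation without relocation.

Simulates liver tissue with periportal/pericentral expression gradients and
one guide that shifts the transcriptional zonation of its cells without
moving them.  The marker score detects the shift while the spatial zone
occupancy of the same cells stays at control levels — dissociating
expression identity from position.
"""

import numpy as np
from scipy.stats import mannwhitneyu

from pmulti import (
    GuideEffect,
    TissueSimConfig,
    segment_zones,
    simulate_screen,
    zonation_score,
    zone_enrichment,
    zscore_vs_controls,
)

guides = {f"ctrl_{i}": GuideEffect() for i in range(3)}
guides["rezone"] = GuideEffect(zonation_shift=-0.45)  # toward pericentral
cfg = TissueSimConfig(n_cells=8000, n_genes=60, field_size_um=1800,
                      guides=guides, lambda_moi=0.31, rng_seed=3)
sim = simulate_screen(cfg)
cells, counts = sim.cells, sim.counts

X = counts.to_numpy(float)
logx = np.log1p(1e4 * X / X.sum(axis=1, keepdims=True))
is_ctrl = cells["is_control"].to_numpy()
labels = cells["guide"].to_numpy(object)
Z = zscore_vs_controls(logx, is_ctrl)

zs = zonation_score(Z, list(counts.columns))
sel = labels == "rezone"
p = mannwhitneyu(zs.loc[sel, "combined"], zs.loc[is_ctrl, "combined"]).pvalue
print(f"combined zonation score (periportal positive): "
      f"rezone {zs.loc[sel, 'combined'].mean():+.1f} vs controls "
      f"{zs.loc[is_ctrl, 'combined'].mean():+.1f} (Mann-Whitney p = {p:.2e})")

pos = cells[["x_um", "y_um"]].to_numpy()
subtype = cells["subtype"].to_numpy()
zmap = segment_zones(pos, np.isin(subtype, ("Hep5", "Hep6")),
                     np.isin(subtype, ("Hep1", "Hep2")), bin_size=50, sigma=0.5)
print(f"zonal map: {zmap.zone.shape[0]}x{zmap.zone.shape[1]} bins at "
      f"{zmap.bin_size:.0f} um, {(zmap.zone == 'A').mean():.0%} zone A "
      "(periportal)")

enr = zone_enrichment(pos, labels, is_ctrl, zmap)
row = enr.loc["rezone"]
print(f"zone-A occupancy of rezone cells: {row['frac_zone_a']:.3f} vs "
      f"control {row['control_frac_zone_a']:.3f} "
      f"(adjusted p = {row['adjusted_p']:.2f})")
print("-> expression says 'pericentral', position says 'unchanged': "
      "transcriptional re-zonation without physical relocation")
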