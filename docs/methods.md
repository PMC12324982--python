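# Methods

This note documents the models, algorithms and numerical choices behind
`pmulti`, in the spirit of a statistical methods appendix.

## Codebook construction

Codewords are binary vectors of length *n* with fixed Hamming weight *w*
and pairwise Hamming distance ≥ *d* (distances between equal-weight
vectors are always even; *d* = 4 corrects any single bit error because a
corrupted vector at distance 1 from its codeword is at distance ≥ 3 from
every other). Construction is a **greedy lexicode**: candidates are all
weight-*w* vectors in lexicographic order of their on-bit position tuples,
and a candidate is accepted iff it is at distance ≥ *d* from every
previously accepted codeword. The pass is deterministic, and validity is
re-checked exhaustively (`verify_codebook` computes the full pairwise
distance matrix). At the parameterizations used for imaging libraries the
greedy pass yields 221 codewords at (21, w=4, d=4) and 756 at
(18, w=6, d=4) — comfortably above the 205 genes and 456 barcodes they
must carry. Target-to-codeword assignment is a seeded uniform permutation;
every unassigned codeword becomes a *blank*, a valid codeword that should
never be detected and whose observed frequency estimates the
misidentification rate.

## Probe windows

Padlock windows are 60-nt stretches split into two 30-nt arms. Each arm
must have GC ∈ [0.30, 0.70] and nearest-neighbor melting temperature in
[60, 80] °C (Tm from SantaLucia nearest-neighbor thermodynamics at 300 mM
Na⁺ and 5 nM probe; both configurable — absolute Tm values shift with the
salt model, but the test oracle applies the same model so rule decisions
are self-consistent). Windows whose donor (5′-phosphorylated) arm begins
with G or C are rejected: G/C at the ligation junction promotes
template-independent ligation. Optional screens: isoform/gene specificity
as the fraction of the window's 17-mers unique to the target (auto-pass
without a reference transcriptome), and rejection of any shared substring
longer than 15 nt with rRNA/tRNA contaminant sequences (implemented as
16-mer set membership). Up to `probes_per_target` accepted windows are
selected greedily 5′→3′ without overlap. Readout/primer insertion is plain
sequence assembly; no chemistry is modeled.

## Molecule decoding

Each molecule carries one intensity per readout bit. The vector is
L2-normalized and binarized **adaptively around the codebook weight**: the
on-bit count *k* is chosen among {w−1, w, w+1} at the largest gap in the
sorted normalized intensities (ties prefer *w*; zero-intensity bits are
never "on"). A top-*w* exact match is assigned with 0 corrections;
otherwise the unique codeword within Hamming distance 1 of the binarized
vector is assigned with 1 correction, and anything else is left
unassigned. The three-weight rule exists because all codewords share
weight *w*: a strictly weight-forced binarization has even distance to
every codeword, so single-bit errors (which produce effective weight
w−1/w+1 vectors) would be uncorrectable. With the adaptive rule, every
single-bit corruption of every codeword decodes uniquely and correctly on
any distance-4 book (verified exhaustively in the tests), and ambiguous
two-error patterns are dropped rather than guessed.

**Misidentification filter.** Four features per assigned molecule: mean
and population variance of the raw bit-intensity vector, spot size, and
mean(on-bit) − mean(off-bit) intensity under the assigned codeword.
Molecules assigned to blanks are labeled negatives, coding assignments
positives; an XGBoost classifier (100 trees, depth 3, η = 0.2, fixed seed)
is trained on a seeded 50% split and scores the rest. Any monotone-score
binary classifier satisfies the same contract. The **adaptive threshold**
is the smallest score cutoff whose retained set has blank fraction ≤ the
target (default 5%); retention is score ≥ threshold, the threshold is
chosen on the held-out calibration half and applied to all molecules, and
an unattainable target retains nothing with a warning. Feasibility is
scanned over all cutoffs (it is not monotone when the top-scoring molecule
is a blank). Both the raw blank fraction (which the 5% target binds) and
the per-codeword-normalized blank rate (mean blank count / mean coding
count) are reported, since both conventions circulate.

## Cells

Molecules are assigned to the segmentation label of the voxel containing
their centroid ("overlap" operationalized as centroid-in-voxel; spot
extent is not modeled). Cells segmented twice in adjacent fields of view
are merged when their centroids from *different* FOVs lie within 5 μm,
transitively via connected components, metadata following the largest-area
member. QC keeps cells with 25–1500 total molecules (bounds inclusive:
the removal rule is "fewer than 25 or more than 1500") and then genes
detected in ≥ 3 remaining cells, in that order; the filter is idempotent.
Normalization scales each cell to 10,000 total counts then applies
log1p. Technical covariates (cell area, total molecules, plus intercept)
are removed feature-wise by one shared least-squares solve; residuals are
z-scored per feature, with residual variance below 10⁻⁸ of the feature's
original variance treated as exactly explained (z = 0) rather than
amplified round-off.

## Perturbation calling

Imaging barcodes call a guide when a cell has **strictly more than 3**
molecules of that barcode. Sequencing calls use per-guide UMI thresholds
(≥); because real screens tune thresholds against on-target knockdown,
which requires data this package does not ship, the default heuristic —
max(5, 10 × median UMI of the guide across cells whose top guide is
different) — is an explicit stand-in, not a reproduction. In both
modalities only cells with exactly one called guide are retained. At low
multiplicity of infection, integrations per cell are Poisson(λ), so the
single-perturbation fraction among transduced cells is
λe^{−λ}/(1−e^{−λ}); the simulator's default λ = 0.31 corresponds to an
85.3% single-barcode fraction, and `moi_from_single_fraction` inverts the
relation.

## Screen statistics

**Z-scoring.** Per batch (e.g. droplet-channel group) and per feature,
z = (x − μ_ctrl)/σ_ctrl with moments from that batch's control cells;
zero control σ gives z = 0 with a warning, and a batch without ≥ 2
controls is an error.

**Energy test.** E(A,B) = 2·mean‖a−b‖ − mean‖a−a′‖ − mean‖b−b′‖ with
within-set means over all ordered pairs including self-pairs (the
V-statistic convention, which keeps E ≥ 0 and E = 0 iff the multisets
coincide). Tests run on the top 20 principal components of the pooled
standardized matrix, computed once. Sampled permutations relabel the
pooled cells preserving group sizes, with
p = (1 + #{E_perm ≥ E_obs})/(1 + B); when the number of distinct
relabelings is small the exact tail over all of them is used instead
(without pseudocount, identity included — note that for equal group sizes
the complement relabeling always ties E_obs, so the smallest attainable
exact p is 2/#partitions). Family-wise error across guides is controlled
by Holm–Šídák: sorted ascending, adj₍ᵢ₎ = 1 − (1 − p₍ᵢ₎)^(m−i),
monotonized; the implementation is cross-checked against statsmodels. At
the default α = 0.05 over 50 guides the per-test bound is ≈ 0.00103, so a
meaningful null calibration needs ≥ 1000 permutations (the FWER test uses
exactly that).

**Differential expression** is two-sided Mann–Whitney per feature on
tp10k-log data (exact for small tie-free samples, tie-corrected normal
otherwise; features constant across both groups get p = 1), adjusted by
Benjamini–Hochberg; gene-set and channel scores use Benjamini–Yekutieli,
which is valid under arbitrary dependence — set scores of overlapping
gene sets are strongly dependent. The reported log2 fold change compares
linearized (expm1) pseudobulk means with a +1 pseudocount. Gene-set
scores are the mean control-relative z over the set's genes, averaged
over a perturbation's cells; significance compares the per-cell set means
to controls. Pseudobulk effect vectors (group mean − control mean,
restricted to the 250 or 1000 genes with the highest control expression)
are compared across perturbations by Pearson correlation over genes; both
mean-log and mean-z phenotypes are supported since they behave
near-identically. KNN label transfer uses majority vote over k = 10
Euclidean neighbors with ties broken by mean neighbor distance then label
order. Cluster merging removes, smallest first, any cluster with fewer
than 10 BH-significant Mann–Whitney DE genes against all other cells,
merging it into the nearest cluster by centroid distance until stable.

## Zonation

The per-cell zonation score sums control-relative z over 7 periportal
markers (positive) minus 16 pericentral markers: all marker z = +1 gives
7 − 16 = −9. Zone segmentation bins cell positions of two hepatocyte
subtype groups into 50-μm 2D histograms, blurs each with a Gaussian of
σ = 0.5 **bin units** (reflective boundary), normalizes each histogram by
its own maximum, and labels every bin by the larger normalized density
(exact ties go to group A and are counted). Zone occupancy per
perturbation is compared to the control fraction by a two-sided binomial
test with BH adjustment — the binomial choice is this package's, as no
standard exists for the comparison. The pipeline deliberately exposes the
dissociation between the two readouts: a perturbation can shift the
marker score (transcriptional re-zonation) while its cells' zone
occupancy stays at control levels (no relocation).

## Simulator

The generator emulates the statistical structure of a zonated-tissue
screen, not its histology. Vein centers sit on a jittered lattice with
checkerboard-alternating pericentral/periportal identity; a cell's
zonation coordinate is d_central/(d_central + d_portal) ∈ [0, 1], and
hepatocyte subtypes Hep1…Hep6 are its quantile bins (Hep1 most
pericentral). Expression is Poisson-lognormal (log-normal noise σ = 0.4
on a Poisson mean — negative-binomial-like overdispersion); zonated
genes' means scale as exp(s·(zc − ½)) with slope ±s (markers always
zonated, defaults s = 2, plus 10 random-sign generic genes), normalized
so population means are slope-free. Baseline gene means are lognormal
weights summing to 600 counts/cell, detection efficiency 0.5.

Guide effects are injected so recovery targets are known by construction:
gene shifts are specified in units of the control-cell standard deviation
of tp10k-log1p expression (calibrated on the simulated control
population, then applied as log-mean shifts, so a +1 shift recovers as a
mean z of ≈ +1 for moderately expressed genes — the log1p nonlinearity
compresses it for very low ones); channel effects multiply lognormal
baseline intensities; zonation shifts move only the *effective*
coordinate used to generate expression, never the position. Transduction
is Poisson(λ = 0.31) with guides uniform over the library; the analysis
label is a cell's sole distinct guide.

Molecule emission: per cell and gene, Binomial(count, 0.5) molecules;
each takes its codeword with independent flips at p(1→0) = 0.05 and
p(0→1) = 0.01, on-bit intensities LogNormal(log 1.0, 0.35) and off-bit
LogNormal(−2.5, 0.6) (≈ 12× dimmer, overlapping at ~2·10⁻⁴ per bit, so a
small unassignable remainder exists even without bit flips — a detection
loss, never a wrong call). Positions are uniform over the cell's mask
pixels; masks are a 2D Voronoi tessellation of cell centers replicated
over 10 z-planes — a stand-in adequate because segmentation itself is out
of scope. Guide UMIs are Poisson(50) for true guides over
Poisson(0.2)-per-guide ambient background.

What the simulator does **not** model — optics and spot overlap, crowding
and segmentation errors, cell-type mixtures beyond the zonation axis,
batch chemistry — bounds what passing tests show: they validate the
statistical machinery under its stated assumptions, not robustness to
real-data artifacts.

## Problem sizes and numerical choices

The bundled checks run at desk scale by design: 50,000-molecule decoding
benchmarks; 200 replicate null screens of 50 guides (15 cells vs 100
controls in 20 dimensions, 1000 permutations) for family-wise error
calibration; recovery screens of 6,000–8,000 cells at ~150–250 cells per
guide. Permutation energy statistics are computed from one pooled
distance matrix per test via membership-matrix products; decoding
distances use the inner-product identity d = |b| + |c| − 2·b·c in 20k-
molecule blocks. All stochastic steps take explicit seeds; identical
configuration reproduces byte-identical outputs, which the pipeline
manifest (versions, seeds, SHA-256 of every output) makes checkable.

## Known limitations

Sequencing-guide thresholds are a documented heuristic; exact
reproduction of any real screen's calls would require its tuned
thresholds. Specificity screens auto-pass without a reference
transcriptome. The simulator's z-space effect injection is exact only up
to the log1p/renormalization nonlinearity (within the ±20% tolerance the
recovery tests assert). Zone segmentation supports two groups; the
binomial occupancy test treats cells as independent, ignoring spatial
autocorrelation within lobules.
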