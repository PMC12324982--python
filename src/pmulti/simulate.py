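"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure of a pooled in vivo
perturbation screen read out by combinatorial FISH in liver tissue:

* vein centers on a jittered lattice alternating pericentral/periportal;
  each cell's zonation coordinate is its relative distance to the nearest
  central versus portal vein, and zonated genes' means scale monotonically
  with it (hepatocyte subtypes are quantile bins of the coordinate);
* overdispersed counts from a Poisson-lognormal model (negative-binomial
  like), with guide transduction Poisson at low multiplicity of infection;
* perturbation effects injected additively on the control-z scale for
  gene programs, multiplicatively for morphology channels, and optionally
  as a shift of the effective zonation coordinate (trans-differentiation
  without movement: positions never change);
* molecule-level bit vectors: the assigned codeword with independent bit
  flips, lognormal on/off intensities, positions uniform within Voronoi
  cell masks; ambient background in the guide UMI matrix.

All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .codebook import Codebook
from .zonation import ZonationMarkers

__all__ = [
    "GuideEffect",
    "TissueSimConfig",
    "SimulatedScreen",
    "simulate_tissue",
    "simulate_transduction_and_effects",
    "simulate_molecules",
    "simulate_guide_umis",
    "simulate_screen",
    "simulate_decoding_benchmark",
]


@dataclass
class GuideEffect:
    """What one guide does to the cells that carry it."""

    gene_shifts: dict = dc_field(default_factory=dict)  # gene -> shift (control-sd units)
    zonation_shift: float = 0.0  # added to the effective zonation coordinate
    channel_factors: dict = dc_field(default_factory=dict)  # channel -> multiplier

    @property
    def is_null(self) -> bool:
        return (
            not self.gene_shifts
            and self.zonation_shift == 0.0
            and not self.channel_factors
        )


@dataclass
class TissueSimConfig:
    """Study conditions for the synthetic screen.

    Defaults reflect the imaging-screen regime: Poisson transduction with
    lambda such that ~85% of transduced cells carry a single guide,
    bit-flip rates 0.05 (1->0) / 0.01 (0->1), detection efficiency 0.5,
    sequencing guide UMIs at depth 50 over ambient 0.2.
    """

    n_cells: int = 1200
    field_size_um: float = 900.0
    vein_spacing_um: float = 300.0
    vein_jitter_um: float = 25.0
    gradient_steepness: float = 2.0
    n_genes: int = 120
    n_extra_zonated: int = 10
    lognormal_noise_sd: float = 0.4
    mean_counts_per_cell: float = 600.0
    n_subtypes: int = 6
    n_batches: int = 1
    # perturbations
    guides: dict = dc_field(default_factory=dict)  # name -> GuideEffect
    lambda_moi: float = 0.31
    # molecule observations
    efficiency: float = 0.5
    p_1_to_0: float = 0.05
    p_0_to_1: float = 0.01
    on_intensity_mu: float = 0.0  # log-space
    on_intensity_sigma: float = 0.35
    off_intensity_mu: float = -2.5
    off_intensity_sigma: float = 0.6
    mean_spot_size_px: float = 8.0
    pixel_size_um: float = 1.0
    n_z_planes: int = 10
    # sequencing arm
    sequencing_depth: float = 50.0
    ambient_umi_rate: float = 0.2
    n_channels: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.efficiency, self.p_1_to_0, self.p_0_to_1):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.lambda_moi <= 0:
            raise ValueError("lambda_moi must be positive")
        if self.vein_spacing_um > self.field_size_um:
            raise ValueError("vein spacing exceeds field size")

    @property
    def control_guides(self) -> list[str]:
        return [g for g, e in self.guides.items() if e.is_null]

    @property
    def channel_names(self) -> list[str]:
        return [f"channel_{i}" for i in range(self.n_channels)]


def _gene_table(config: TissueSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene names, baseline means and zonation slopes.

    Marker genes are always present and zonated (periportal markers slope
    up with the periportal coordinate, pericentral markers slope down);
    `n_extra_zonated` generic genes get random-sign slopes.
    """
    m = ZonationMarkers()
    names = list(m.periportal) + list(m.pericentral)
    n_generic = config.n_genes - len(names)
    if n_generic < 0:
        raise ValueError(f"n_genes must be at least {len(names)}")
    names += [f"Gene_{i:03d}" for i in range(n_generic)]
    weights = rng.lognormal(0.0, 1.0, size=config.n_genes)
    base_mean = config.mean_counts_per_cell * weights / weights.sum()
    slope = np.zeros(config.n_genes)
    s = config.gradient_steepness
    slope[: len(m.periportal)] = s
    slope[len(m.periportal) : len(names) - n_generic] = -s
    extra = rng.choice(
        np.arange(len(names) - n_generic, config.n_genes),
        size=min(config.n_extra_zonated, n_generic),
        replace=False,
    )
    slope[extra] = rng.choice([-s, s], size=len(extra))
    return pd.DataFrame({"gene": names, "base_mean": base_mean, "slope": slope})


def _zonated_means(
    zc: np.ndarray, genes: pd.DataFrame
) -> np.ndarray:
    """Per-cell per-gene Poisson means; zonated genes scale with exp(slope*(zc-1/2))."""
    mu = genes["base_mean"].to_numpy()[None, :] * np.exp(
        genes["slope"].to_numpy()[None, :] * (zc[:, None] - 0.5)
    )
    # keep the population-average mean at base_mean for a uniform coordinate
    s = genes["slope"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(s != 0, (np.exp(s / 2) - np.exp(-s / 2)) / s, 1.0)
    return mu / norm[None, :]


def _draw_counts(
    mu: np.ndarray, sd_log: float, rng: np.random.Generator
) -> np.ndarray:
    noise = rng.lognormal(-0.5 * sd_log**2, sd_log, size=mu.shape)
    return rng.poisson(mu * noise)


def simulate_tissue(
    config: TissueSimConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate cell positions, zonation and baseline expression.

    Returns ``(cells, counts, genes)``: per-cell metadata (position,
    zonation coordinate, subtype, batch), the integer count matrix as a
    DataFrame (cells x genes), and the gene table with the generating
    means and slopes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    L = config.field_size_um
    sp = config.vein_spacing_um
    # jittered lattice, checkerboard-alternating central/portal veins
    gx, gy = np.meshgrid(
        np.arange(sp / 2, L, sp), np.arange(sp / 2, L, sp), indexing="ij"
    )
    jitter = rng.normal(0, config.vein_jitter_um, size=gx.shape + (2,))
    centers = np.column_stack([gx.ravel(), gy.ravel()]) + jitter.reshape(-1, 2)
    parity = (np.add.outer(np.arange(gx.shape[0]), np.arange(gx.shape[1])) % 2).ravel()
    central = centers[parity == 0]
    portal = centers[parity == 1]
    if len(central) == 0 or len(portal) == 0:
        raise ValueError("vein lattice too coarse for the field")

    xy = rng.uniform(0, L, size=(config.n_cells, 2))
    d_c, _ = cKDTree(central).query(xy)
    d_p, _ = cKDTree(portal).query(xy)
    zc = d_c / (d_c + d_p)  # 0 = pericentral, 1 = periportal

    q = np.quantile(zc, np.linspace(0, 1, config.n_subtypes + 1)[1:-1])
    subtype_idx = np.digitize(zc, q)
    subtype = np.array([f"Hep{i + 1}" for i in subtype_idx])

    genes = _gene_table(config, rng)
    mu = _zonated_means(zc, genes)
    counts = _draw_counts(mu, config.lognormal_noise_sd, rng)

    cells = pd.DataFrame(
        {
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "zonation_coord": zc,
            "subtype": subtype,
            "batch": [f"batch{i % config.n_batches}" for i in range(config.n_cells)],
        },
        index=pd.Index([f"cell_{i}" for i in range(config.n_cells)], name="cell_id"),
    )
    counts_df = pd.DataFrame(counts, index=cells.index, columns=genes["gene"])
    return cells, counts_df, genes


def simulate_transduction_and_effects(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    config: TissueSimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Poisson transduction and perturbation effects.

    Integrations per cell are Poisson(lambda); guides are uniform over the
    library.  Guide effects are applied by regenerating the affected
    counts with shifted generating means: gene shifts are calibrated in
    units of the control-cell standard deviation of tp10k-log1p
    expression (so a +1 shift recovers as a +1 mean z), zonation shifts
    move the *effective* coordinate used for expression (positions are
    untouched), and channel factors multiply lognormal baseline channel
    intensities.

    Returns updated ``(cells, counts, channels)``.
    """
    guide_names = list(config.guides)
    n = len(cells)
    cells = cells.copy()
    counts = counts.copy()
    k = rng.poisson(config.lambda_moi, size=n)
    guide_lists = [
        sorted(rng.choice(guide_names, size=ki, replace=True)) if ki and guide_names else []
        for ki in k
    ]
    cells["true_guides"] = guide_lists
    cells["n_integrations"] = k
    # a cell's analysis label is its sole distinct guide, if any
    cells["guide"] = [
        g[0] if len(set(g)) == 1 and g else None for g in guide_lists
    ]

    ctrl_set = set(config.control_guides)
    is_control_cell = np.array(
        [len(g) == 0 or set(g) <= ctrl_set for g in guide_lists]
    )
    cells["is_control"] = is_control_cell

    # control-scale calibration: sd of tp10k-log1p expression per gene
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    logx = np.log1p(1e4 * X / totals)
    s_g = logx[is_control_cell].std(axis=0)
    s_g[s_g == 0] = 1.0

    gene_idx = {g: j for j, g in enumerate(counts.columns)}
    zc = cells["zonation_coord"].to_numpy().copy()
    zc_eff = zc.copy()
    log_shift = np.zeros_like(X)
    for i, glist in enumerate(guide_lists):
        for g in glist:
            eff = config.guides[g]
            zc_eff[i] = np.clip(zc_eff[i] + eff.zonation_shift, 0.0, 1.0)
            for gene, delta in eff.gene_shifts.items():
                j = gene_idx[gene]
                log_shift[i, j] += delta * s_g[j]
    cells["zonation_coord_effective"] = zc_eff

    moved = np.nonzero(zc_eff != zc)[0]
    shifted = np.nonzero((log_shift != 0).any(axis=1))[0]
    redo = np.union1d(moved, shifted)
    if len(redo):
        mu = _zonated_means(zc_eff[redo], genes) * np.exp(log_shift[redo])
        counts.iloc[redo] = _draw_counts(mu, config.lognormal_noise_sd, rng)

    base = rng.lognormal(np.log(1000.0), 0.3, size=(n, config.n_channels))
    factors = np.ones((n, config.n_channels))
    ch_idx = {c: j for j, c in enumerate(config.channel_names)}
    for i, glist in enumerate(guide_lists):
        for g in glist:
            for ch, f in config.guides[g].channel_factors.items():
                factors[i, ch_idx[ch]] *= f
    channels = pd.DataFrame(
        base * factors, index=cells.index, columns=config.channel_names
    )
    return cells, counts, channels


def _voronoi_labels(
    xy_um: np.ndarray, field_size_um: float, pixel_size_um: float, n_z: int
) -> np.ndarray:
    """3D label image (z, y, x): nearest cell center per pixel, 1-based."""
    npix = int(np.ceil(field_size_um / pixel_size_um))
    coords = (np.arange(npix) + 0.5) * pixel_size_um
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    _, lab = cKDTree(xy_um).query(np.column_stack([xx.ravel(), yy.ravel()]))
    plane = (lab + 1).reshape(npix, npix).astype(np.int32)
    return np.repeat(plane[None, :, :], n_z, axis=0)


def simulate_molecules(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    codebook: Codebook,
    config: TissueSimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Emit molecule observations and the matching 3D label image.

    Per cell per gene, the detected molecule count is Binomial(count,
    efficiency); each molecule's bit vector is its gene's codeword with
    independent flips at the configured rates, on/off intensities are
    lognormal, and positions are uniform within the cell's Voronoi mask.
    Truth columns ``true_name`` and ``true_cell`` accompany the
    observables.
    """
    if codebook.n_blanks == 0:
        raise ValueError("codebook must contain blank codewords")
    gene_names = [g for g in counts.columns if g in set(codebook.names)]
    if not gene_names:
        raise ValueError("no count-matrix genes found in the codebook")
    xy = cells[["x_um", "y_um"]].to_numpy()
    labels3d = _voronoi_labels(
        xy, config.field_size_um, config.pixel_size_um, config.n_z_planes
    )

    C = counts[gene_names].to_numpy()
    det = rng.binomial(C, config.efficiency)
    cell_rep, gene_rep = np.nonzero(det)
    reps = det[cell_rep, gene_rep]
    mol_cell = np.repeat(cell_rep, reps)
    mol_gene = np.repeat(gene_rep, reps)
    n_mol = len(mol_cell)

    name_to_row = {n: i for i, n in enumerate(codebook.names)}
    code_rows = np.array([name_to_row[g] for g in gene_names])
    true_bits = codebook.bits[code_rows[mol_gene]].astype(bool)
    flips = np.where(
        true_bits,
        rng.random(true_bits.shape) < config.p_1_to_0,
        rng.random(true_bits.shape) < config.p_0_to_1,
    )
    bits = true_bits ^ flips
    intens = np.where(
        bits,
        rng.lognormal(config.on_intensity_mu, config.on_intensity_sigma, bits.shape),
        rng.lognormal(config.off_intensity_mu, config.off_intensity_sigma, bits.shape),
    )

    # positions: uniform over the pixels of the molecule's cell mask
    plane = labels3d[0]
    npix = plane.shape[0]
    flat_order = np.argsort(plane.ravel(), kind="stable")
    pix_per_cell = np.bincount(plane.ravel(), minlength=len(cells) + 1)
    offsets = np.concatenate([[0], np.cumsum(pix_per_cell)])
    lab = mol_cell + 1  # 1-based labels
    pick = offsets[lab] + rng.integers(0, np.maximum(pix_per_cell[lab], 1))
    pix = flat_order[pick]
    py, px = np.divmod(pix, npix)
    pos = np.column_stack(
        [
            (px + rng.random(n_mol)) * config.pixel_size_um,
            (py + rng.random(n_mol)) * config.pixel_size_um,
        ]
    )
    z = rng.integers(0, config.n_z_planes, size=n_mol)
    half = config.field_size_um / 2
    fov = (pos[:, 0] >= half).astype(int) + 2 * (pos[:, 1] >= half).astype(int)

    mols = pd.DataFrame(
        {
            "molecule_id": np.arange(n_mol),
            "fov": fov,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z": z,
            "size_px": 1 + rng.poisson(config.mean_spot_size_px, size=n_mol),
            "true_name": np.array(gene_names, dtype=object)[mol_gene],
            "true_cell": cells.index.to_numpy()[mol_cell],
        }
    )
    for b in range(codebook.n_bits):
        mols[f"bit_{b}"] = intens[:, b]
    return mols, labels3d


def simulate_guide_umis(
    cells: pd.DataFrame, config: TissueSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Guide UMI matrix: Poisson(depth) for true guides over ambient noise."""
    guide_names = list(config.guides)
    M = rng.poisson(config.ambient_umi_rate, size=(len(cells), len(guide_names)))
    gidx = {g: j for j, g in enumerate(guide_names)}
    for i, glist in enumerate(cells["true_guides"]):
        for g in glist:
            M[i, gidx[g]] += rng.poisson(config.sequencing_depth)
    return pd.DataFrame(M, index=cells.index, columns=guide_names)


@dataclass
class SimulatedScreen:
    """Bundle of ground truth and observables for one simulated screen."""

    config: TissueSimConfig
    cells: pd.DataFrame
    counts: pd.DataFrame
    genes: pd.DataFrame
    channels: pd.DataFrame
    guide_umis: pd.DataFrame


def simulate_screen(
    config: TissueSimConfig, seed: int | None = None
) -> SimulatedScreen:
    """Tissue + transduction + effects + sequencing arm in one call."""
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    cells, counts, genes = simulate_tissue(config, rng)
    cells, counts, channels = simulate_transduction_and_effects(
        cells, counts, genes, config, rng
    )
    umis = simulate_guide_umis(cells, config, rng)
    return SimulatedScreen(
        config=config,
        cells=cells,
        counts=counts,
        genes=genes,
        channels=channels,
        guide_umis=umis,
    )


def simulate_decoding_benchmark(
    codebook: Codebook,
    n_molecules: int,
    p_1_to_0: float = 0.05,
    p_0_to_1: float = 0.01,
    seed: int = 0,
    on_mu: float = 0.0,
    on_sigma: float = 0.35,
    off_mu: float = -2.5,
    off_sigma: float = 0.6,
    mean_spot_size_px: float = 8.0,
) -> pd.DataFrame:
    """Molecule-table benchmark for the decoder and blank filter.

    Draws molecules uniformly from the codebook's coding codewords,
    applies independent bit flips and lognormal on/off intensities, and
    returns a molecule table with truth column ``true_name``.  Blank
    codewords emit no molecules; any blank assignment downstream is a
    misidentification.
    """
    rng = np.random.default_rng(seed)
    coding = np.nonzero(~codebook.is_blank)[0]
    if len(coding) == 0:
        raise ValueError("codebook has no coding codewords")
    rows = rng.choice(coding, size=n_molecules)
    true_bits = codebook.bits[rows].astype(bool)
    flips = np.where(
        true_bits,
        rng.random(true_bits.shape) < p_1_to_0,
        rng.random(true_bits.shape) < p_0_to_1,
    )
    bits = true_bits ^ flips
    intens = np.where(
        bits,
        rng.lognormal(on_mu, on_sigma, bits.shape),
        rng.lognormal(off_mu, off_sigma, bits.shape),
    )
    names = np.array(codebook.names, dtype=object)
    mols = pd.DataFrame(
        {
            "molecule_id": np.arange(n_molecules),
            "fov": 0,
            "x_um": rng.uniform(0, 100, n_molecules),
            "y_um": rng.uniform(0, 100, n_molecules),
            "z": rng.integers(0, 10, n_molecules),
            "size_px": 1 + rng.poisson(mean_spot_size_px, size=n_molecules),
            "true_name": names[rows],
        }
    )
    for b in range(codebook.n_bits):
        mols[f"bit_{b}"] = intens[:, b]
    return mols
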