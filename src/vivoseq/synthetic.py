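"""Synthetic cohorts with planted ground truth.

Two generators emulate the statistical structure the analysis assumes:

* ``gen_calcium_cohort`` — stimulus-locked calcium transients (exponential
  decay, instantaneous rise at a random latency inside the first second of
  each designed positive stimulus window) on a noisy baseline, plus a
  background trace, under the standard protocol (5-s grating, 15-s
  inter-stimulus interval, 5 repetitions, 30 frames/s).
* ``gen_expression_cohort`` — a Smart-seq2-like negative-binomial count
  matrix (log-normal per-cell size factors) with planted LS-vs-NS
  differential genes, planted co-expression modules (one tied to the LS
  indicator), marker-structured cell types (excitatory / inhibitory neurons,
  with designed astrocyte / oligodendrocyte / ex-in doublets), and designed
  per-cell QC failures.

Two canonical fixtures mirror the cohort bookkeeping of a 24-mouse V1
recording campaign: 83 recorded neurons of which 63 pass the calcium
response criteria, and a 63-cell sequencing cohort of which 58 survive the
metric filters, 53 survive doublet removal, split 41 LS / 12 NS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import FluorescenceTrace, StimulusProtocol
from .qc import CellQCRecord, ExpressionMatrix, MARKER_SETS

#: amplitude floor (ΔF/F) standing in for the noise SD when noise_sd = 0, so
#: noiseless designs still carry visible transients
NOISELESS_AMPLITUDE_FLOOR = 0.1
#: noise excursions are truncated at this multiple of noise_sd, below the
#: 2x-SD event threshold, emulating the sub-Gaussian tails of temporally
#: filtered imaging noise and keeping designed response counts identifiable
NOISE_CLIP_SD = 1.8


@dataclass(frozen=True)
class CalciumSimParams:
    n_cells: int
    n_reps: int = 5
    stim_duration_s: float = 5.0
    isi_s: float = 15.0
    frame_rate_hz: float = 30.0
    transient_amplitude_snr: float = 5.0
    transient_decay_s: float = 1.0
    noise_sd: float = 0.02
    response_design: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_reps < 1:
            raise ValueError("n_cells and n_reps must be >= 1")
        if min(self.stim_duration_s, self.isi_s, self.frame_rate_hz) <= 0:
            raise ValueError("durations and frame rate must be positive")
        if self.noise_sd < 0 or self.transient_decay_s <= 0:
            raise ValueError("noise_sd must be >= 0 and decay > 0")
        if self.response_design is not None:
            if len(self.response_design) != self.n_cells:
                raise ValueError("response_design length must equal n_cells")
            if any(not (0 <= k <= self.n_reps) for k in self.response_design):
                raise ValueError("response_design entries must lie in [0, n_reps]")


@dataclass(frozen=True)
class ExprSimParams:
    n_ls: int = 41
    n_ns: int = 12
    n_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 3.0
    n_modules: int = 5
    module_size: int = 30
    trait_module_index: int = 0
    doublet_design: tuple[tuple[int, str], ...] = ()  # (cell index, kind)
    metric_failure_design: tuple[tuple[int, str], ...] = ()  # (cell index, reason)
    mean_library_size: float = 5e5
    dispersion: float = 0.2
    #: planted DE genes are drawn from genes with at least this expected FPKM,
    #: so the planted fold change is expressible on the pseudocounted
    #: FPKM + 1 scale
    de_min_base_fpkm: float = 40.0
    #: cap on the total expected extra library mass the up-regulated planted
    #: genes may add, as a fraction of the library; limits the compositional
    #: distortion of measured FPKM fold changes
    de_max_planted_mass: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_ls, self.n_ns) < 0 or self.n_genes < 1:
            raise ValueError("counts must be non-negative")
        n_named = sum(len(v) for v in MARKER_SETS.values()) + len(_PANEL_GENE_SYMBOLS)
        if self.n_de_genes + self.n_modules * self.module_size + n_named > self.n_genes:
            raise ValueError("more planted genes than n_genes")
        n_cells = self.n_ls + self.n_ns
        for idx, kind in self.doublet_design:
            if not (0 <= idx < n_cells) or kind not in ("astro", "oligo", "ex-in"):
                raise ValueError(f"bad doublet design entry ({idx}, {kind})")
        for idx, reason in self.metric_failure_design:
            if not (0 <= idx < n_cells) or reason not in ("cdna", "mito", "genes"):
                raise ValueError(f"bad metric failure entry ({idx}, {reason})")
        if self.dispersion <= 0 or self.mean_library_size <= 0:
            raise ValueError("dispersion and library size must be positive")


@dataclass
class SyntheticTruth:
    cell_labels: dict[str, str] = field(default_factory=dict)
    de_gene_ids: set[str] = field(default_factory=set)
    module_assignments: dict[str, int] = field(default_factory=dict)
    doublet_ids: set[str] = field(default_factory=set)
    metric_fail_ids: dict[str, str] = field(default_factory=dict)
    designed_positives: dict[str, int] = field(default_factory=dict)
    trait_module_index: int | None = None
    de_direction: dict[str, int] = field(default_factory=dict)  # gene -> +1 / -1


# ---------------------------------------------------------------------------
# calcium cohorts
# ---------------------------------------------------------------------------

def default_protocol(params: CalciumSimParams) -> StimulusProtocol:
    """Protocol with a lead-in of one inter-stimulus interval before onset 1."""
    period = params.stim_duration_s + params.isi_s
    onsets = tuple(params.isi_s + r * period for r in range(params.n_reps))
    return StimulusProtocol(
        onsets_s=onsets,
        stim_duration_s=params.stim_duration_s,
        isi_s=params.isi_s,
        frame_rate_hz=params.frame_rate_hz,
    )


def gen_calcium_cohort(
    params: CalciumSimParams,
) -> tuple[list[FluorescenceTrace], StimulusProtocol, SyntheticTruth]:
    """Simulate a cohort of cell-body / background fluorescence trace pairs.

    Each designed positive repetition receives one transient: instantaneous
    rise at a uniform latency in the first second of the stimulus window,
    exponential decay (``transient_decay_s``), peak amplitude
    ``transient_amplitude_snr x noise_sd`` (amplitude floor 0.1 ΔF/F when
    noise-free).  The background trace is a constant with small independent
    jitter; the cell trace is background + baseline 1.0 x (1 + signal + noise)
    so the net trace carries ``noise_sd`` of near-Gaussian noise whose
    excursions are truncated at 1.8 x noise_sd (see ``NOISE_CLIP_SD``).
    """
    rng = np.random.default_rng(params.seed)
    protocol = default_protocol(params)
    period = params.stim_duration_s + params.isi_s
    total_s = params.isi_s + params.n_reps * period
    n_frames = int(round(total_s * params.frame_rate_hz))
    t = np.arange(n_frames) / params.frame_rate_hz

    if params.response_design is not None:
        design = list(params.response_design)
    else:
        design = list(rng.integers(0, params.n_reps + 1, size=params.n_cells))

    amp_scale = params.noise_sd if params.noise_sd > 0 else NOISELESS_AMPLITUDE_FLOOR
    amplitude = params.transient_amplitude_snr * amp_scale

    traces: list[FluorescenceTrace] = []
    truth = SyntheticTruth()
    for i in range(params.n_cells):
        cell_id = f"cell_{i:03d}"
        k = int(design[i])
        chosen = rng.choice(params.n_reps, size=k, replace=False) if k else []
        signal = np.zeros(n_frames)
        for r in sorted(int(r) for r in chosen):
            onset = protocol.onsets_s[r]
            latency = rng.uniform(0.0, min(1.0, params.stim_duration_s))
            t0 = onset + latency
            rise = t >= t0
            signal[rise] += amplitude * np.exp(-(t[rise] - t0) / params.transient_decay_s)
        noise = rng.normal(0.0, params.noise_sd, size=n_frames)
        if params.noise_sd > 0:
            clip = NOISE_CLIP_SD * params.noise_sd
            noise = np.clip(noise, -clip, clip)
        bg = 2.0 + rng.normal(0.0, params.noise_sd / 20.0, size=n_frames)
        net = 1.0 * (1.0 + signal + noise)
        traces.append(
            FluorescenceTrace(
                cell_id=cell_id,
                f_cell=bg + net,
                f_background=bg,
                frame_rate_hz=params.frame_rate_hz,
            )
        )
        truth.designed_positives[cell_id] = k
        truth.cell_labels[cell_id] = "LS" if k >= 4 else ("NS" if k <= 1 else "excluded")
    return traces, protocol, truth


def gen_calcium_fixture(
    seed: int = 3,
) -> tuple[list[FluorescenceTrace], StimulusProtocol, SyntheticTruth]:
    """Canonical 83-trace cohort: 41 designed LS, 22 designed NS, 20 excluded.

    Transient amplitude dominates the noise so classification is unambiguous;
    the response criteria retain 63 cells.
    """
    design = (
        [4, 5] * 21  # 42 -> trim to 41 cells with >= 4 positives
    )[:41] + (
        [0, 1] * 11  # 22 cells with <= 1 positive
    ) + (
        [2, 3] * 10  # 20 cells with 2-3 positives -> excluded
    )
    params = CalciumSimParams(
        n_cells=83,
        response_design=tuple(design),
        transient_amplitude_snr=20.0,
        noise_sd=0.01,
        seed=seed,
    )
    return gen_calcium_cohort(params)


# ---------------------------------------------------------------------------
# expression cohorts
# ---------------------------------------------------------------------------

_ALL_MARKERS = tuple(g for genes in MARKER_SETS.values() for g in genes)
#: marker transcript lengths kept short so even one fragment is detectable
_MARKER_LENGTH_BP = 1500

#: channel / receptor symbols carried by every simulated cohort so the
#: gene-panel stage resolves against synthetic matrices
_PANEL_GENE_SYMBOLS = (
    "Atp1a1", "Atp1a3", "Atp1b1", "Clcn3", "Scn1a", "Scn2a", "Kcna1",
    "Kcnb1", "Kcnq2", "Cacna1a", "Cacnb4", "Kcnma1", "Gria1", "Gria2",
    "Grid1", "Grik2", "Grin1", "Grin2a", "Gabra1", "Gabrb2", "Chrna4",
    "Htr1a", "Grm1", "Gabbr1", "Chrm1", "Drd1", "Cnr1",
)


def gen_expression_cohort(
    params: ExprSimParams,
) -> tuple[ExpressionMatrix, list[CellQCRecord], SyntheticTruth]:
    """Simulate a genes x cells count matrix with planted structure.

    Returns counts (FPKM conversion is done downstream so the normalization
    stage is exercised), per-cell QC metadata, and the planted truth.
    """
    rng = np.random.default_rng(params.seed)
    n_cells = params.n_ls + params.n_ns
    cell_ids = [f"cell_{i:03d}" for i in range(n_cells)]
    labels = ["LS"] * params.n_ls + ["NS"] * params.n_ns
    is_ls = np.array([lab == "LS" for lab in labels])

    n_named = len(_ALL_MARKERS) + len(_PANEL_GENE_SYMBOLS)
    gene_ids = list(_ALL_MARKERS) + list(_PANEL_GENE_SYMBOLS) + [
        f"gene_{i:05d}" for i in range(params.n_genes - n_named)
    ]
    n_genes = params.n_genes
    lengths = rng.integers(500, 10_001, size=n_genes).astype(float)
    lengths[: len(_ALL_MARKERS)] = _MARKER_LENGTH_BP
    biotype = np.where(rng.random(n_genes) < 0.95, "protein_coding", "lincRNA")
    biotype[:n_named] = "protein_coding"

    # base per-gene means, scaled so the expected library is mean_library_size
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base *= params.mean_library_size / base.sum()
    base[: len(_ALL_MARKERS)] = 0.0  # markers handled explicitly below

    # choose planted genes among non-marker genes; DE genes need enough base
    # expression for the fold-change rule to be attainable after pseudocounts
    candidates = np.arange(len(_ALL_MARKERS), n_genes)
    base_fpkm = base * 1e9 / (lengths * params.mean_library_size)
    # per-gene count budget so the up-regulated half of the planted genes adds
    # at most de_max_planted_mass of extra expected library mass
    n_up = max(params.n_de_genes / 2.0, 1.0)
    count_cap = (
        params.de_max_planted_mass * params.mean_library_size
        / ((2.0 ** params.de_log2fc - 1.0) * n_up)
    )
    well_expressed = candidates[
        (base_fpkm[candidates] >= params.de_min_base_fpkm)
        & (base[candidates] <= count_cap)
    ]
    if len(well_expressed) < params.n_de_genes:
        raise ValueError("not enough well-expressed genes to plant DE genes")
    de_idx = rng.choice(well_expressed, size=params.n_de_genes, replace=False)
    remaining = np.setdiff1d(candidates, de_idx)
    n_module_genes = params.n_modules * params.module_size
    module_idx = rng.choice(remaining, size=n_module_genes, replace=False)

    # per-cell log-normal size factors
    size_factors = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)

    # expected mean matrix (genes x cells)
    mu = np.outer(base, size_factors)

    truth = SyntheticTruth(trait_module_index=(
        params.trait_module_index if params.n_modules else None
    ))
    truth.cell_labels = dict(zip(cell_ids, labels))

    # planted differential genes: alternate up/down in LS cells
    fold = 2.0 ** params.de_log2fc
    for j, g in enumerate(de_idx):
        direction = 1 if j % 2 == 0 else -1
        truth.de_gene_ids.add(gene_ids[g])
        truth.de_direction[gene_ids[g]] = direction
        mu[g, is_ls] *= fold if direction > 0 else 1.0 / fold

    # planted co-expression modules: shared latent factor per module
    factors = rng.normal(0.0, 1.0, size=(params.n_modules, n_cells))
    if params.n_modules:
        z_ls = (is_ls - is_ls.mean()) / (is_ls.std() if is_ls.std() > 0 else 1.0)
        factors[params.trait_module_index] = z_ls + rng.normal(0.0, 0.5, size=n_cells)
    for m in range(params.n_modules):
        block = module_idx[m * params.module_size : (m + 1) * params.module_size]
        loadings = rng.uniform(0.8, 1.2, size=len(block))
        for g, a in zip(block, loadings):
            truth.module_assignments[gene_ids[g]] = m
            mu[g] = np.maximum(base[g], 50.0) * 2.0 ** (a * factors[m])

    # negative-binomial sampling
    r = 1.0 / params.dispersion
    counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9)))

    # cell types and marker expression: excitatory vs inhibitory neurons
    marker_pos = {g: i for i, g in enumerate(_ALL_MARKERS)}
    ex_cell = rng.random(n_cells) < 0.8

    def _express(gene: str, cells: np.ndarray, mean: float = 100.0) -> None:
        row = marker_pos[gene]
        vals = rng.negative_binomial(r, r / (r + mean), size=int(cells.sum()))
        counts[row, cells] = np.maximum(vals, 1)  # designed-positive guarantee

    _express("Slc17a7", ex_cell)
    _express("Neurod2", ex_cell)
    _express("Gad1", ~ex_cell)
    _express("Gad2", ~ex_cell)
    # S100b is expressed at low level in some neurons (harmless: product needs
    # Gfap and Aqp4 too); Gfap/Aqp4/Olig1/Olig2/Mbp stay zero in neurons.
    s100b_cells = rng.random(n_cells) < 0.3
    if s100b_cells.any():
        _express("S100b", s100b_cells, mean=5.0)

    # designed doublets co-express a second cell type's full marker set
    for idx, kind in params.doublet_design:
        cells = np.zeros(n_cells, dtype=bool)
        cells[idx] = True
        if kind == "astro":
            for g in MARKER_SETS["astro"]:
                _express(g, cells)
        elif kind == "oligo":
            for g in MARKER_SETS["oligo"]:
                _express(g, cells)
        else:  # ex-in: both neuron marker sets positive
            for g in MARKER_SETS["ex"] + MARKER_SETS["in"]:
                _express(g, cells)
        truth.doublet_ids.add(cell_ids[idx])

    # designed metric failures
    cdna = rng.normal(2500.0, 400.0, size=n_cells).clip(min=1200.0)
    mito = rng.uniform(0.01, 0.15, size=n_cells)
    coding = biotype == "protein_coding"
    for idx, reason in params.metric_failure_design:
        truth.metric_fail_ids[cell_ids[idx]] = reason
        if reason == "cdna":
            cdna[idx] = rng.uniform(300.0, 900.0)
        elif reason == "mito":
            mito[idx] = rng.uniform(0.30, 0.50)
        else:  # low detected-gene count: silence all but ~800 genes
            keep = rng.choice(n_genes, size=800, replace=False)
            mask = np.ones(n_genes, dtype=bool)
            mask[keep] = False
            counts[mask, idx] = 0
            if counts[:, idx].sum() == 0:  # keep the library non-empty
                counts[keep[0], idx] = max(counts[keep[0], idx], 1)

    values = pd.DataFrame(counts, index=gene_ids, columns=cell_ids, dtype=float)
    gene_meta = pd.DataFrame(
        {"length_bp": lengths, "biotype": biotype}, index=gene_ids
    )
    matrix = ExpressionMatrix(values, gene_meta, value_kind="counts")

    # detected protein-coding genes at >= 1 FPKM, for the QC metadata
    lib = values.sum(axis=0)
    fpkm = values.mul(1e9).div(pd.Series(lengths, index=gene_ids), axis=0).div(lib, axis=1)
    n_detected = (fpkm.loc[coding] >= 1.0).sum(axis=0)

    records = [
        CellQCRecord(
            cell_id=c,
            cdna_pg_ul=float(cdna[i]),
            mito_fraction=float(mito[i]),
            n_genes_detected=int(n_detected[c]),
            label=labels[i],
        )
        for i, c in enumerate(cell_ids)
    ]
    return matrix, records, truth


def gen_qc_fixture(
    seed: int = 1,
) -> tuple[ExpressionMatrix, list[CellQCRecord], SyntheticTruth]:
    """Canonical 63-cell sequencing cohort mirroring the staged QC bookkeeping.

    By design: 2 cells fail the cDNA-concentration filter, 2 the mitochondrial
    fraction, 1 the detected-gene count (five distinct cells); among the 58
    metric-passing cells 4 are astrocyte/oligodendrocyte doublets and 1 is an
    excitatory-inhibitory doublet; the 53 survivors carry 41 LS and 12 NS
    labels.
    """
    # cells 41..62 are NS; the ten designed removals all fall on NS cells so
    # the survivors split 41 LS / 12 NS
    params = ExprSimParams(
        n_ls=41,
        n_ns=22,
        metric_failure_design=(
            (41, "cdna"), (42, "cdna"), (43, "mito"), (44, "mito"), (45, "genes"),
        ),
        doublet_design=(
            (46, "astro"), (47, "astro"), (48, "oligo"), (49, "oligo"), (50, "ex-in"),
        ),
        seed=seed,
    )
    return gen_expression_cohort(params)
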