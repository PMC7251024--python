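"""Staged single-cell expression quality control.

Pipeline order: FPKM normalization → gene filter (protein-coding, detected at
≥ 1 FPKM) → per-cell metric filters (cDNA concentration, mitochondrial read
fraction, detected-gene count) → multiplicative marker-product doublet
removal.  Also provides cohort-structure summaries: per-cell detected-gene
counts and the cell-cell Pearson correlation matrix with median within-group
correlations for LS and NS subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Cell-filter thresholds; comparisons are strict exactly as worded
# (< 1,000 pg/uL, > 25% mitochondrial, < 1,000 detected protein-coding genes).
CDNA_MIN_PG_UL = 1000.0
MITO_MAX_FRACTION = 0.25
MIN_GENES_DETECTED = 1000
#: detection threshold for the gene filter (inclusive: "at least 1 FPKM")
GENE_FPKM_MIN = 1.0

#: mutually exclusive cell-type marker sets used for multiplicative doublet scores
MARKER_SETS: dict[str, tuple[str, ...]] = {
    "astro": ("Gfap", "S100b", "Aqp4"),
    "oligo": ("Olig1", "Olig2", "Mbp"),
    "ex": ("Slc17a7", "Neurod2"),
    "in": ("Gad1", "Gad2"),
}


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with per-gene length and biotype.

    ``values`` is a genes x cells DataFrame (index = gene ids, columns = cell
    ids); ``gene_meta`` is indexed by gene id with columns ``length_bp`` and
    ``biotype``; ``value_kind`` is ``"counts"`` or ``"fpkm"``.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "fpkm"):
            raise ValueError("value_kind must be 'counts' or 'fpkm'")
        if not self.values.index.equals(self.gene_meta.index):
            raise ValueError("values and gene_meta must share the gene index")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if "length_bp" in self.gene_meta and (self.gene_meta["length_bp"] <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(cells)], self.gene_meta, self.value_kind)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = self.values.index.isin(set(genes))
        return ExpressionMatrix(
            self.values.loc[keep], self.gene_meta.loc[keep], self.value_kind
        )


@dataclass(frozen=True)
class CellQCRecord:
    cell_id: str
    cdna_pg_ul: float
    mito_fraction: float
    n_genes_detected: int
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not (0.0 <= self.mito_fraction <= 1.0):
            raise ValueError("mito_fraction must lie in [0, 1]")
        if self.n_genes_detected < 0 or self.cdna_pg_ul < 0:
            raise ValueError("metrics must be non-negative")


@dataclass(frozen=True)
class DoubletScore:
    cell_id: str
    s_astro: float
    s_oligo: float
    s_ex: float
    s_in: float

    @property
    def s_ex_in(self) -> float:
        return self.s_ex * self.s_in

    @property
    def is_doublet(self) -> bool:
        return self.s_astro > 0 or self.s_oligo > 0 or self.s_ex_in > 0


@dataclass
class QCReport:
    """Staged keep/remove bookkeeping; every input cell lands in exactly one bin."""

    input_cells: list[str]
    removed: dict[str, list[str]] = field(default_factory=dict)  # reason -> cells
    stage_order: tuple[str, ...] = ("cdna", "mito", "genes", "doublet")
    kept_cells: list[str] = field(default_factory=list)
    n_genes_input: int = 0
    n_genes_kept: int = 0

    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def reason_of(self, cell_id: str) -> str | None:
        for reason, cells in self.removed.items():
            if cell_id in cells:
                return reason
        return None

    def summary(self) -> dict:
        return {
            "n_input": len(self.input_cells),
            "removed_per_stage": {k: len(self.removed.get(k, [])) for k in self.stage_order},
            "n_kept": len(self.kept_cells),
            "n_genes_input": self.n_genes_input,
            "n_genes_kept": self.n_genes_kept,
        }


def compute_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm[g, c] = count[g, c] * 1e9 / (length_bp[g] * total_counts[c]).
    """
    if matrix.value_kind != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    if "length_bp" not in matrix.gene_meta:
        raise ValueError("gene lengths missing")
    lib = matrix.values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"zero library size for cells: {bad}")
    lengths = matrix.gene_meta["length_bp"].astype(float)
    fpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return ExpressionMatrix(fpkm, matrix.gene_meta, value_kind="fpkm")


def filter_genes(matrix: ExpressionMatrix, mode: str = "any") -> ExpressionMatrix:
    """Keep protein-coding genes detected at ≥ 1 FPKM.

    ``mode="any"`` (default) keeps genes whose maximum FPKM across cells is
    ≥ 1; ``mode="all"`` requires ≥ 1 FPKM in every cell.
    """
    if matrix.value_kind != "fpkm":
        raise ValueError("filter_genes expects an FPKM matrix")
    coding = matrix.gene_meta["biotype"] == "protein_coding"
    if mode == "any":
        detected = matrix.values.max(axis=1) >= GENE_FPKM_MIN
    elif mode == "all":
        detected = matrix.values.min(axis=1) >= GENE_FPKM_MIN
    else:
        raise ValueError("mode must be 'any' or 'all'")
    keep = coding & detected
    if not keep.any():
        warnings.warn("gene filter removed every gene")
    return ExpressionMatrix(
        matrix.values.loc[keep], matrix.gene_meta.loc[keep], "fpkm"
    )


def filter_cells_metrics(records: list[CellQCRecord]) -> dict[str, list[str]]:
    """Stage the three per-cell metric filters; returns reason -> removed cells.

    Stages run in order cDNA → mito → genes; a cell is removed at the first
    stage it fails, so the removal lists are disjoint.
    """
    removed: dict[str, list[str]] = {"cdna": [], "mito": [], "genes": []}
    for rec in records:
        if rec.cdna_pg_ul < CDNA_MIN_PG_UL:
            removed["cdna"].append(rec.cell_id)
        elif rec.mito_fraction > MITO_MAX_FRACTION:
            removed["mito"].append(rec.cell_id)
        elif rec.n_genes_detected < MIN_GENES_DETECTED:
            removed["genes"].append(rec.cell_id)
    return removed


def doublet_scores(matrix: ExpressionMatrix) -> list[DoubletScore]:
    """Multiplicative marker co-expression scores per cell, on FPKM values.

    S_astro = Gfap x S100b x Aqp4; S_oligo = Olig1 x Olig2 x Mbp;
    S_ex = Slc17a7 x Neurod2; S_in = Gad1 x Gad2; S_ex-in = S_ex x S_in.
    A marker gene absent from the matrix is treated as uniformly zero.
    """
    if matrix.value_kind != "fpkm":
        raise ValueError("doublet_scores expects an FPKM matrix")

    def _row(gene: str) -> pd.Series:
        if gene in matrix.values.index:
            return matrix.values.loc[gene]
        warnings.warn(f"marker gene {gene} absent; treated as zero expression")
        return pd.Series(0.0, index=matrix.cell_ids)

    prods = {}
    for name, genes in MARKER_SETS.items():
        prod = pd.Series(1.0, index=matrix.cell_ids)
        for g in genes:
            prod = prod * _row(g)
        prods[name] = prod
    return [
        DoubletScore(
            cell_id=c,
            s_astro=float(prods["astro"][c]),
            s_oligo=float(prods["oligo"][c]),
            s_ex=float(prods["ex"][c]),
            s_in=float(prods["in"][c]),
        )
        for c in matrix.cell_ids
    ]


def run_qc(
    matrix: ExpressionMatrix,
    records: list[CellQCRecord],
    gene_filter_mode: str = "any",
) -> tuple[QCReport, ExpressionMatrix]:
    """Full staged QC: FPKM → gene filter → metric filters → doublet removal."""
    rec_ids = [r.cell_id for r in records]
    if set(rec_ids) != set(matrix.cell_ids):
        raise ValueError("cell ids of matrix and QC records do not match")

    fpkm = compute_fpkm(matrix) if matrix.value_kind == "counts" else matrix
    filtered = filter_genes(fpkm, mode=gene_filter_mode)

    report = QCReport(input_cells=list(matrix.cell_ids))
    report.n_genes_input = len(matrix.gene_ids)
    report.n_genes_kept = len(filtered.gene_ids)

    report.removed = filter_cells_metrics(records)
    metric_removed = {c for cells in report.removed.values() for c in cells}
    surviving = [c for c in matrix.cell_ids if c not in metric_removed]

    scores = doublet_scores(filtered.subset_cells(surviving))
    report.removed["doublet"] = [s.cell_id for s in scores if s.is_doublet]
    doublet_removed = set(report.removed["doublet"])

    report.kept_cells = [c for c in surviving if c not in doublet_removed]
    return report, filtered.subset_cells(report.kept_cells)


def detected_genes(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.Series:
    """Per-cell count of genes with FPKM strictly greater than ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (matrix.values > threshold).sum(axis=0)


def cohort_correlation(
    matrix: ExpressionMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cell-cell Pearson correlations on log2(FPKM + 1) and per-group medians.

    Returns the symmetric cell x cell correlation matrix and the median of the
    off-diagonal within-group correlations for each label.
    """
    log_vals = np.log2(matrix.values + 1.0)
    constant = log_vals.std(axis=0, ddof=0) == 0
    corr = log_vals.corr(method="pearson")  # pandas leaves NaN for constant cells
    if constant.any():
        warnings.warn("constant cell vectors produce undefined correlations")
    medians: dict[str, float] = {}
    for grp in pd.unique(labels):
        cells = [c for c in matrix.cell_ids if labels.get(c) == grp]
        if len(cells) < 2:
            continue
        block = corr.loc[cells, cells].to_numpy()
        off = block[np.triu_indices(len(cells), k=1)]
        medians[str(grp)] = float(np.nanmedian(off))
    return corr, medians
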