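"""Ion-channel / receptor gene-panel comparison between LS and NS cells.

Panels are named gene groups (Na+/K+-ATPase subunits, glutamatergic AMPA /
kainate / NMDA receptors, GABA-A receptors, muscarinic receptors, ...),
resolved against the expression matrix by explicit gene list or by symbol
prefix.  Per panel the per-cell summed FPKM of member genes is compared
between groups with Welch's unpaired two-sample t-test; paired t-tests serve
before/after treatment comparisons of calcium event counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import ExpressionMatrix

#: default panel membership by gene-symbol prefix (curated, overridable)
DEFAULT_PANEL_PREFIXES: dict[str, tuple[str, ...]] = {
    "Na+/K+-ATPase": ("Atp1a", "Atp1b"),
    "Cl- channel": ("Clcn",),
    "Na+ channel": ("Scn",),
    "K+ channel": ("Kcna", "Kcnb", "Kcnc", "Kcnd", "Kcnq", "Kcnh"),
    "Ca2+ channel": ("Cacna", "Cacnb", "Cacng"),
    "KCa channel": ("Kcnma", "Kcnn"),
    "AMPA": ("Gria",),
    "delta-Glu": ("Grid",),
    "kainate": ("Grik",),
    "NMDA": ("Grin",),
    "GABA": ("Gabra", "Gabrb", "Gabrg", "Gabrd"),
    "nACh": ("Chrna", "Chrnb"),
    "5-HT": ("Htr",),
    "mGlu": ("Grm",),
    "mGABA": ("Gabbr",),
    "mACh": ("Chrm",),
    "DA": ("Drd",),
    "2-AG": ("Cnr",),
}


@dataclass(frozen=True)
class PanelDefinition:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("panel gene list must be non-empty")


@dataclass(frozen=True)
class PanelResult:
    panel: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p_value: float
    n_genes: int

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unpaired two-sample t with Satterthwaite df; two-sided p.

    Two identical constant groups give (0, n_a + n_b - 2, 1.0) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf, float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def resolve_panels(
    matrix: ExpressionMatrix,
    panels: list[PanelDefinition] | None = None,
) -> list[PanelDefinition]:
    """Restrict panel gene lists to genes present in the matrix.

    Without explicit panels the default symbol-prefix table is expanded
    against the matrix's gene ids.  Empty resolved panels are dropped with a
    warning.
    """
    gene_ids = list(matrix.gene_ids)
    if panels is None:
        panels = [
            PanelDefinition(name, tuple(g for g in gene_ids
                                        if any(g.startswith(p) for p in prefixes)) or ("-",))
            for name, prefixes in DEFAULT_PANEL_PREFIXES.items()
        ]
        panels = [p for p in panels if p.genes != ("-",)]
    resolved = []
    present = set(gene_ids)
    for p in panels:
        genes = tuple(g for g in p.genes if g in present)
        if not genes:
            warnings.warn(f"panel {p.name!r} has no genes in the matrix; skipped")
            continue
        resolved.append(PanelDefinition(p.name, genes))
    return resolved


def panel_compare(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    panels: list[PanelDefinition] | None = None,
    group_a: str = "LS",
    group_b: str = "NS",
    per_gene: bool = False,
) -> pd.DataFrame:
    """Welch comparison of panel expression between two labeled groups.

    Default statistic is the per-cell sum of member-gene FPKM; with
    ``per_gene`` every member gene is tested separately.
    """
    resolved = resolve_panels(matrix, panels)
    cells_a = [c for c in matrix.cell_ids if labels.get(c) == group_a]
    cells_b = [c for c in matrix.cell_ids if labels.get(c) == group_b]
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both groups need at least 2 cells")
    rows = []
    for panel in resolved:
        sub = matrix.values.loc[list(panel.genes)]
        units = [(panel.name, sub.sum(axis=0))] if not per_gene else [
            (f"{panel.name}:{g}", sub.loc[g]) for g in panel.genes
        ]
        for name, series in units:
            va, vb = series[cells_a].to_numpy(), series[cells_b].to_numpy()
            t, df, p = welch_t(va, vb)
            res = PanelResult(
                panel=name,
                mean_a=float(va.mean()), sd_a=float(va.std(ddof=1)),
                mean_b=float(vb.mean()), sd_b=float(vb.std(ddof=1)),
                t=t, df=df, p_value=p, n_genes=len(panel.genes),
            )
            rows.append(
                {
                    "panel": res.panel, "n_genes": res.n_genes,
                    f"mean_{group_a}": res.mean_a, f"sd_{group_a}": res.sd_a,
                    f"mean_{group_b}": res.mean_b, f"sd_{group_b}": res.sd_b,
                    "t": res.t, "df": res.df, "p_value": res.p_value,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def paired_response_test(before, after) -> tuple[float, float, float]:
    """Paired t-test on before/after event counts; two-sided p.

    All-zero differences give (0, n-1, 1.0); a constant non-zero difference is
    a sign-determined effect reported with p = 0 and a warning.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError("before/after must be equal-length 1-D vectors")
    if b.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, float(b.size - 1), 1.0
        warnings.warn("constant non-zero paired differences: sign-determined effect")
        return (np.inf if d[0] > 0 else -np.inf, float(b.size - 1), 0.0)
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(b.size - 1), float(res.pvalue)


def load_panels_tsv(path) -> list[PanelDefinition]:
    """Read a two-column (panel, gene) TSV into panel definitions."""
    frame = pd.read_csv(path, sep="\t")
    if not {"panel", "gene"}.issubset(frame.columns):
        raise ValueError("panels TSV needs 'panel' and 'gene' columns")
    return [
        PanelDefinition(name, tuple(grp["gene"]))
        for name, grp in frame.groupby("panel", sort=False)
    ]
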