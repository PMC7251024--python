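"""Two-group LS-vs-NS differential expression.

Per gene: fold change log2((mean_LS + 1) / (mean_NS + 1)) on FPKM, p-value
from Welch's two-sample t-test on log2(FPKM + 1), Benjamini–Hochberg
adjustment across tested genes.  A gene is called differentially expressed
when p_adj < 0.05 and |log2FC| > 2.5; called genes are ranked by descending
fold change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import ExpressionMatrix

PADJ_MAX = 0.05
LOG2FC_MIN = 2.5


def de_test(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    group_a: str = "LS",
    group_b: str = "NS",
) -> pd.DataFrame:
    """Per-gene two-group test; returns gene-indexed results.

    Columns: log2fc, p_value, p_adj, is_deg, rank (rank only among DEGs,
    NaN elsewhere).  Degenerate genes (zero variance in both groups with
    equal means) get p = 1.
    """
    cells_a = [c for c in matrix.cell_ids if labels.get(c) == group_a]
    cells_b = [c for c in matrix.cell_ids if labels.get(c) == group_b]
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both groups need at least 2 cells")

    va = matrix.values[cells_a].to_numpy(dtype=float)
    vb = matrix.values[cells_b].to_numpy(dtype=float)
    log2fc = np.log2((va.mean(axis=1) + 1.0) / (vb.mean(axis=1) + 1.0))

    la, lb = np.log2(va + 1.0), np.log2(vb + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes produce nan -> handled below
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)

    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    is_deg = (p_adj < PADJ_MAX) & (np.abs(log2fc) > LOG2FC_MIN)

    res = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "p_adj": p_adj, "is_deg": is_deg},
        index=matrix.gene_ids,
    )
    res["rank"] = np.nan
    ranked = rank_degs(res)
    res.loc[ranked, "rank"] = np.arange(1, len(ranked) + 1, dtype=float)
    return res


def rank_degs(results: pd.DataFrame) -> list[str]:
    """DEG gene ids sorted by descending log2fc; ties by ascending p, then id."""
    degs = results[results["is_deg"]]
    order = degs.sort_values(
        by=["log2fc", "p_value"],
        ascending=[False, True],
        kind="mergesort",  # stable so the gene-id index breaks remaining ties
    )
    return list(order.index)


def top_expressed(
    matrix: ExpressionMatrix, labels: pd.Series, group: str = "LS", n: int = 200
) -> list[str]:
    """Top-n genes by mean FPKM within one group; ties by gene id."""
    cells = [c for c in matrix.cell_ids if labels.get(c) == group]
    if not cells:
        raise ValueError(f"group {group!r} has no cells")
    means = matrix.values[cells].mean(axis=1)
    if n > len(means):
        warnings.warn(f"requested top {n} of {len(means)} genes; returning all")
        n = len(means)
    frame = means.to_frame("mean").reset_index(names="gene")
    frame = frame.sort_values(by=["mean", "gene"], ascending=[False, True], kind="mergesort")
    return list(frame["gene"].head(n))
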