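"""Weighted co-expression module detection and module-trait correlation.

A deliberately compact re-implementation of the weighted co-expression
workflow applied to differentially expressed genes: signed-absolute soft
adjacency |r|^beta, average-linkage dendrogram on 1 - adjacency (optionally
1 - TOM), a scanned fixed-height cut with a minimum module size in place of
dynamic tree cutting, eigengene-based module merging, and Pearson
module-eigengene / trait correlation with the binary light-sensitivity
indicator carried as its own "white" pseudo-module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .qc import ExpressionMatrix

#: module colors by decreasing size; "grey" = unassigned, "white" = the trait
MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "lightgreen", "lightyellow", "royalblue", "darkred",
)
GREY = "grey"
TRAIT_MODULE = "white"


@dataclass(frozen=True)
class ModuleConfig:
    soft_power: int = 6
    min_cluster_size: int = 10
    merge_cor_threshold: float = 0.75
    use_tom: bool = False

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not (0.0 <= self.merge_cor_threshold <= 1.0):
            raise ValueError("merge_cor_threshold must lie in [0, 1]")


@dataclass
class Eigengene:
    module: str
    scores: pd.Series  # per-cell, unit variance
    explained_variance: float


@dataclass
class ModuleTraitResult:
    correlation: pd.DataFrame  # (modules + trait) square matrix
    p_values: pd.DataFrame
    linkage: np.ndarray = field(repr=False)  # average-linkage tree on 1 - correlation


def _log_expr(matrix: ExpressionMatrix) -> pd.DataFrame:
    return np.log2(matrix.values + 1.0)


def build_adjacency(matrix: ExpressionMatrix, config: ModuleConfig) -> pd.DataFrame:
    """Soft-threshold adjacency a_ij = |pearson(g_i, g_j)|^beta on log2(FPKM+1).

    Constant genes get zero off-diagonal weight (with a warning).  When
    ``config.use_tom`` the topological overlap transform is applied.
    """
    log_vals = _log_expr(matrix)
    if log_vals.shape[1] < 4:
        raise ValueError("need at least 4 cells to build the network")
    if log_vals.shape[0] < config.min_cluster_size:
        raise ValueError("fewer genes than min_cluster_size")
    constant = log_vals.std(axis=1, ddof=0) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes given zero adjacency")
    corr = np.corrcoef(log_vals.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    adj = np.abs(corr) ** config.soft_power
    np.fill_diagonal(adj, 1.0)
    if config.use_tom:
        adj = _topological_overlap(adj)
    return pd.DataFrame(adj, index=matrix.gene_ids, columns=matrix.gene_ids)


def _topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM: shared-neighbor overlap normalized by the smaller connectivity."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l_mat = a @ a
    k = a.sum(axis=1)
    k_min = np.minimum.outer(k, k)
    tom = (l_mat + a) / (k_min + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def cluster_genes(adjacency: pd.DataFrame) -> np.ndarray:
    """Average-linkage (UPGMA) tree on dissimilarity 1 - adjacency."""
    diss = 1.0 - adjacency.to_numpy(dtype=float)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    return hierarchy.linkage(squareform(diss, checks=False), method="average")


def cut_modules(
    linkage: np.ndarray,
    matrix: ExpressionMatrix,
    config: ModuleConfig,
) -> pd.Series:
    """Assign genes to color-labeled modules.

    The merge heights of the tree are scanned for the cut maximizing the
    number of clusters of size >= min_cluster_size (ties resolved toward the
    lower cut).  Undersized clusters become "grey".  Modules whose eigengenes
    correlate above ``merge_cor_threshold`` are merged iteratively, largest
    pairs first.  Colors are assigned by decreasing module size.
    """
    genes = matrix.gene_ids
    heights = np.unique(linkage[:, 2])
    # candidate cuts between successive merge heights, capped below the root
    # (99% of the top height) so unstructured trees yield no module at all
    cuts = (heights[:-1] + heights[1:]) / 2.0
    cuts = cuts[cuts <= 0.99 * heights[-1]]
    if cuts.size == 0:
        return pd.Series(GREY, index=genes, dtype=object)
    best_labels, best_key = None, (-1, -1)
    for cut in cuts:
        flat = hierarchy.fcluster(linkage, t=cut, criterion="distance")
        sizes = np.bincount(flat)
        big = sizes[1:] >= config.min_cluster_size
        # primary: most clusters of admissible size; secondary: fewest grey
        # genes; remaining ties resolve toward the lower cut
        key = (int(big.sum()), int(sizes[1:][big].sum()))
        if key > best_key:
            best_labels, best_key = flat, key
    assert best_labels is not None

    assignment = pd.Series(GREY, index=genes, dtype=object)
    clusters = []
    for lab in np.unique(best_labels):
        members = genes[best_labels == lab]
        if len(members) >= config.min_cluster_size:
            clusters.append(list(members))
    clusters.sort(key=lambda m: (-len(m), m[0]))

    clusters = _merge_similar(clusters, matrix, config)
    clusters.sort(key=lambda m: (-len(m), m[0]))
    for color, members in zip(MODULE_PALETTE, clusters):
        assignment.loc[members] = color
    if len(clusters) > len(MODULE_PALETTE):
        for i, members in enumerate(clusters[len(MODULE_PALETTE):]):
            assignment.loc[members] = f"module{len(MODULE_PALETTE) + i + 1}"
    return assignment


def _merge_similar(
    clusters: list[list[str]], matrix: ExpressionMatrix, config: ModuleConfig
) -> list[list[str]]:
    """Iteratively merge the most correlated eigengene pair above the threshold."""
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        scores = [
            _eigengene_scores(matrix.subset_genes(c))[0] for c in clusters
        ]
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                r = float(np.corrcoef(scores[i], scores[j])[0, 1])
                if r > config.merge_cor_threshold and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


def _eigengene_scores(sub: ExpressionMatrix) -> tuple[np.ndarray, float]:
    """First-PC per-cell scores of standardized log expression; unit variance.

    Returns (scores, explained-variance fraction).
    """
    x = _log_expr(sub).to_numpy(dtype=float)  # genes x cells
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    try:
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0].copy()
        expl = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 0.0
    except np.linalg.LinAlgError:
        warnings.warn("singular module; eigengene falls back to the module mean")
        scores, expl = z.mean(axis=0), 0.0
    sd_scores = scores.std(ddof=0)
    if sd_scores > 0:
        scores = (scores - scores.mean()) / sd_scores
    # orient toward the module's mean expression profile
    mean_profile = z.mean(axis=0)
    if np.std(mean_profile) > 0 and np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    return scores, expl


def module_eigengene(
    matrix: ExpressionMatrix, assignment: pd.Series, module: str
) -> Eigengene:
    """Eigengene (first principal component) of one non-grey module."""
    if module == GREY:
        raise ValueError("grey is the unassigned bucket, not a module")
    members = assignment.index[assignment == module]
    if len(members) == 0:
        raise ValueError(f"module {module!r} has no genes")
    sub = matrix.subset_genes(members)
    scores, expl = _eigengene_scores(sub)
    return Eigengene(
        module=module,
        scores=pd.Series(scores, index=matrix.cell_ids),
        explained_variance=float(expl),
    )


def all_eigengenes(matrix: ExpressionMatrix, assignment: pd.Series) -> pd.DataFrame:
    """Cells x modules eigengene table for every non-grey module."""
    mods = [m for m in pd.unique(assignment) if m != GREY]
    mods.sort(key=lambda m: (-int((assignment == m).sum()), m))
    data = {m: module_eigengene(matrix, assignment, m).scores for m in mods}
    return pd.DataFrame(data, index=matrix.cell_ids)


def module_trait(eigengenes: pd.DataFrame, trait: pd.Series) -> ModuleTraitResult:
    """Correlate eigengenes (and pairs) with the binary trait as module "white".

    p-values come from the exact t-transform t = r sqrt((n-2)/(1-r^2)) with
    n - 2 degrees of freedom, two-sided.
    """
    trait = trait.reindex(eigengenes.index).astype(float)
    if trait.isna().any():
        raise ValueError("trait missing for some cells")
    if trait.nunique() < 2:
        raise ValueError("constant trait")
    table = eigengenes.copy()
    table[TRAIT_MODULE] = trait
    n = len(table)
    corr = table.corr(method="pearson")
    r = corr.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    pvals = pd.DataFrame(p, index=corr.index, columns=corr.columns)
    diss = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(np.clip(diss, 0, None), checks=False), "average")
    return ModuleTraitResult(correlation=corr, p_values=pvals, linkage=link)


def detect_modules(
    matrix: ExpressionMatrix, config: ModuleConfig | None = None
) -> pd.Series:
    """Convenience wrapper: adjacency → dendrogram → modules."""
    config = config or ModuleConfig()
    adj = build_adjacency(matrix, config)
    link = cluster_genes(adj)
    return cut_modules(link, matrix, config)
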