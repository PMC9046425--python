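"""Gene module detection, eigengenes, and module-trait statistics.

Modules are branches of an average-linkage hierarchical clustering of the
topological-overlap dissimilarity, cut statically at a quantile of the merge
heights; branches below the minimum size are pooled into an ``"unassigned"``
sink (the conventional grey module). Each module is summarized by its
eigengene — the first principal component of the module's standardized
expression — and related to the binary trait by Pearson (point-biserial)
correlation. Per-gene statistics are gene significance (GS, absolute
correlation with the trait) and module membership (MM, correlation with the
own-module eigengene); intramodular hubs are the genes with the largest |MM|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "ModuleEigengenes",
    "ModuleTraitStats",
    "detect_modules",
    "module_eigengenes",
    "module_trait_stats",
]

UNASSIGNED = "unassigned"


@dataclass
class ModuleAssignment:
    """Partition of genes into modules plus the dendrogram that produced it."""

    labels: pd.Series  # gene -> module id ("unassigned" = sink)
    min_module_size: int
    cut_height: float
    merge_tree: np.ndarray  # scipy linkage matrix

    @property
    def module_ids(self) -> list[str]:
        ids = [m for m in self.labels.unique() if m != UNASSIGNED]
        return sorted(ids, key=lambda m: (-(self.labels == m).sum(), m))

    def genes_in(self, module_id: str) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


@dataclass
class ModuleEigengenes:
    """First principal component per module, unit variance, sign-anchored."""

    me: pd.DataFrame  # modules x samples
    explained_variance: pd.Series  # fraction of module variance captured


@dataclass
class ModuleTraitStats:
    """Module-level trait correlations and per-gene GS/MM statistics."""

    module_trait: pd.DataFrame  # module, cor, p, p.adj
    gene_stats: pd.DataFrame  # gene, module, MM, GS, p.GS

    def significant_modules(self, alpha: float = 0.05) -> list[str]:
        hits = self.module_trait[self.module_trait["p"] <= alpha]
        return list(hits.sort_values(["p", "module"])["module"])


def detect_modules(diss_tom: pd.DataFrame, min_module_size: int = 30,
                   cut_height_quantile: float = 0.5,
                   merge_me_cor: float | None = None,
                   expr: pd.DataFrame | None = None) -> ModuleAssignment:
    """Average-linkage clustering of dissTOM with a static quantile-height cut.

    Branches below ``min_module_size`` go to the ``"unassigned"`` sink. Module
    ids are assigned by decreasing size ("M1", "M2", ...), deterministic given
    the input. If ``merge_me_cor`` is set (requires ``expr``), modules whose
    eigengenes correlate above it are iteratively merged.
    """
    genes = list(diss_tom.index)
    if len(genes) < min_module_size:
        raise ValueError("fewer genes than min_module_size")
    d = np.asarray(diss_tom, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10) or np.abs(np.diag(d)).max() > 1e-10:
        raise ValueError("dissimilarity must be symmetric with zero diagonal")
    condensed = squareform(d, checks=False)
    tree = linkage(condensed, method="average")
    cut = float(np.quantile(tree[:, 2], cut_height_quantile))
    raw = fcluster(tree, t=cut, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene"), dtype=object)
    sizes = pd.Series(raw).value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    # deterministic naming: by decreasing size, ties by smallest member gene id
    def sort_key(c):
        members = [genes[i] for i in np.flatnonzero(raw == c)]
        return (-len(members), min(members))

    for rank, c in enumerate(sorted(big, key=sort_key), start=1):
        labels.iloc[np.flatnonzero(raw == c)] = f"M{rank}"

    assignment = ModuleAssignment(labels, min_module_size, cut, tree)
    if merge_me_cor is not None:
        if expr is None:
            raise ValueError("merge_me_cor requires the expression matrix")
        assignment = _merge_similar_modules(assignment, expr, merge_me_cor)
    n_mod = len(assignment.module_ids)
    logger.info("detected %d modules (+%d unassigned genes) at cut height %.4f",
                n_mod, int((assignment.labels == UNASSIGNED).sum()), cut)
    return assignment


def _merge_similar_modules(assignment: ModuleAssignment, expr: pd.DataFrame,
                           threshold: float) -> ModuleAssignment:
    labels = assignment.labels.copy()
    while True:
        ids = [m for m in labels.unique() if m != UNASSIGNED]
        if len(ids) < 2:
            break
        me = _eigengene_frame(expr, labels, ids)
        cor = np.corrcoef(me.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] < threshold:
            break
        keep, absorb = sorted([ids[i], ids[j]])
        labels[labels == absorb] = keep
    # re-rank names by size after merging
    ids = [m for m in labels.unique() if m != UNASSIGNED]
    ordered = sorted(ids, key=lambda m: (-(labels == m).sum(), min(labels.index[labels == m])))
    rename = {old: f"M{rank}" for rank, old in enumerate(ordered, start=1)}
    labels = labels.map(lambda m: rename.get(m, m))
    return ModuleAssignment(labels, assignment.min_module_size, assignment.cut_height,
                            assignment.merge_tree)


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (values - mean) / sd


def _module_eigengene(values: np.ndarray) -> tuple[np.ndarray, float]:
    """First right singular vector of standardized expression, unit variance."""
    z = _standardize_rows(values)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    explained = float(s[0] ** 2 / np.sum(s**2)) if s.sum() > 0 else 0.0
    sd = me.std(ddof=1)
    if sd > 0:
        me = (me - me.mean()) / sd
    if np.corrcoef(me, z.mean(axis=0))[0, 1] < 0:
        me = -me
    return me, explained


def _eigengene_frame(expr: pd.DataFrame, labels: pd.Series, ids: list[str]) -> pd.DataFrame:
    rows = {}
    for m in ids:
        values = expr.loc[labels.index[labels == m]].to_numpy(dtype=float)
        rows[m], _ = _module_eigengene(values)
    return pd.DataFrame(rows, index=expr.columns).T


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> ModuleEigengenes:
    """Eigengene (first PC of standardized module expression) per module.

    The sign is anchored so each eigengene correlates nonnegatively with the
    module's mean standardized expression.
    """
    rows, ev = {}, {}
    for m in assignment.module_ids:
        values = expr.loc[assignment.genes_in(m)].to_numpy(dtype=float)
        rows[m], ev[m] = _module_eigengene(values)
    me = pd.DataFrame(rows, index=expr.columns).T
    me.index.name = "module"
    return ModuleEigengenes(me=me, explained_variance=pd.Series(ev, name="explained_variance"))


def _cor_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = pearsonr(x, y)
    return float(r), float(p)


def module_trait_stats(expr: pd.DataFrame, me: ModuleEigengenes, metadata: pd.DataFrame,
                       assignment: ModuleAssignment) -> ModuleTraitStats:
    """Module-trait correlations plus per-gene GS and MM.

    The trait is its 0/1 encoding, so cor(ME, trait) is the point-biserial
    correlation; two-sided p-values come from the exact t transform on n - 2
    degrees of freedom. Module p-values are reported raw with a BH-adjusted
    column alongside.
    """
    trait = metadata.loc[expr.columns, "trait"].to_numpy(dtype=float)
    if len(np.unique(trait)) < 2:
        raise ValueError("trait is constant")
    if len(trait) < 4:
        raise ValueError("need at least 4 samples")

    records = []
    for m in me.me.index:
        r, p = _cor_with_p(me.me.loc[m].to_numpy(), trait)
        records.append({"module": m, "cor": r, "p": p})
    module_trait = pd.DataFrame(records, columns=["module", "cor", "p"])
    if len(module_trait):
        module_trait["p.adj"] = multipletests(module_trait["p"], method="fdr_bh")[1]
    else:
        module_trait["p.adj"] = []

    gene_rows = []
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        module = assignment.labels[gene]
        if x.std() == 0:
            gs, p_gs, mm = 0.0, 1.0, np.nan
        else:
            r_t, p_gs = _cor_with_p(x, trait)
            gs = abs(r_t)
            mm = (
                _cor_with_p(me.me.loc[module].to_numpy(), x)[0]
                if module in me.me.index
                else np.nan
            )
        gene_rows.append({"gene": gene, "module": module, "MM": mm, "GS": gs, "p.GS": p_gs})
    gene_stats = pd.DataFrame(gene_rows).set_index("gene")
    return ModuleTraitStats(module_trait=module_trait, gene_stats=gene_stats)


def hub_genes(stats: ModuleTraitStats, module_id: str, top: int = 10) -> pd.DataFrame:
    """Top intramodular hub genes of a module ranked by |MM|."""
    sub = stats.gene_stats[stats.gene_stats["module"] == module_id].copy()
    sub["absMM"] = sub["MM"].abs()
    return sub.sort_values(["absMM", "gene"], ascending=[False, True]).head(top).drop(columns="absMM")
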