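"""Over-representation analysis and the TF-miRNA-mRNA regulatory network.

Module gene lists are tested against user-supplied gene-set collections (GMT:
pathways, transcription-factor targets, miRNA targets) with the one-sided
hypergeometric upper tail, Benjamini-Hochberg adjusted within each collection.
Enriched regulators and their targets among the key genes are then assembled
into a directed regulator -> target network, optionally augmented with
curated literature edges, exportable to GraphML and SIF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "hypergeom_ora", "build_regnet"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus a source tag (pathway | tf_targets | mirna_targets)."""

    sets: dict[str, list[str]]
    source: str = "pathway"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def hypergeom_ora(query: set[str] | list[str], collection: GeneSetCollection,
                  universe: set[str] | list[str], min_size: int = 5,
                  alpha: float = 0.05, significant_only: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the universe before the size filter; the p-value
    is the upper tail P(X >= overlap) so an empty overlap gives p = 1 exactly.
    BH adjustment runs across the tested sets of this collection only.
    Returns rows sorted by adjusted then raw p, filtered to
    ``p.adj <= alpha`` when ``significant_only``.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    if query == universe:
        warnings.warn("query equals the universe; enrichment is degenerate (all p = 1)")

    M, N = len(universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & universe
        n = len(members)
        if n < min_size:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "set": name,
                "source": collection.source,
                "overlap": k,
                "set_size": n,
                "query_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "source", "overlap", "set_size", "query_size",
                     "universe_size", "p", "p.adj", "genes"]
        )
    result = pd.DataFrame(rows)
    result["p.adj"] = multipletests(result["p"], method="fdr_bh")[1]
    result = result.sort_values(["p.adj", "p", "set"], kind="stable").reset_index(drop=True)
    if significant_only:
        result = result[result["p.adj"] <= alpha].reset_index(drop=True)
    return result[["set", "source", "overlap", "set_size", "query_size",
                   "universe_size", "p", "p.adj", "genes"]]


def build_regnet(key_genes: pd.DataFrame, tf_sets: GeneSetCollection | None = None,
                 mirna_sets: GeneSetCollection | None = None,
                 enriched_tfs: list[str] | None = None,
                 enriched_mirnas: list[str] | None = None,
                 extra_edges: pd.DataFrame | None = None) -> nx.DiGraph:
    """Assemble the directed TF/miRNA -> gene regulatory network.

    ``key_genes`` is indexed by gene id with an optional ``module`` column.
    For every enriched regulator (all regulators in the collection if the
    enriched list is None) an edge is drawn to each key gene in its target
    set. ``extra_edges`` (columns source, target, optional evidence) appends
    curated literature interactions; unknown endpoints there are an error.
    """
    graph = nx.DiGraph()
    for gene, row in key_genes.iterrows():
        graph.add_node(str(gene), kind="gene", module=str(row.get("module", "")))

    targets = set(map(str, key_genes.index))
    for collection, enriched, kind in (
        (tf_sets, enriched_tfs, "TF"),
        (mirna_sets, enriched_mirnas, "miRNA"),
    ):
        if collection is None:
            continue
        regulators = sorted(collection.sets) if enriched is None else list(enriched)
        for reg in regulators:
            hit = sorted(set(collection.sets.get(reg, ())) & targets)
            if not hit:
                continue
            if reg not in graph:
                graph.add_node(reg, kind=kind)
            for gene in hit:
                if reg != gene:
                    graph.add_edge(reg, gene, evidence=collection.source)

    if extra_edges is not None:
        for _, row in extra_edges.iterrows():
            src, dst = str(row["source"]), str(row["target"])
            for node in (src, dst):
                if node not in graph:
                    raise ValueError(f"unknown node in extra_edges: {node!r}")
            if src != dst:
                graph.add_edge(src, dst, evidence=str(row.get("evidence", "literature")))
    logger.info("regulatory network: %d nodes, %d edges", graph.number_of_nodes(),
                graph.number_of_edges())
    return graph
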