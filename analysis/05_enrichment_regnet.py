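"""Over-representation analysis and the regulator-target network.

Tests each trait-significant module against the synthetic pathway, TF-target
and miRNA-target collections (hypergeometric upper tail, BH within each
collection, set size >= 5, adjusted p <= 0.05), then assembles the directed
regulator -> key-gene network from the enriched regulators and exports it as
GraphML and SIF under results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from coexnet import io
from coexnet.enrichment import GeneSetCollection, build_regnet, hypergeom_ora

DATA = Path("results/data")
PRE = Path("results/preprocessed")
NET = Path("results/network")
OUT = Path("results/enrichment")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expr = io.read_expression(PRE / "expr_adjusted.tsv")
    labels = pd.read_csv(NET / "modules.tsv", sep="\t", index_col=0)["module"]
    gene_stats = pd.read_csv(NET / "gene_stats.tsv", sep="\t", index_col=0)
    significant = io.read_json(NET / "summary.json")["significant_modules"]
    universe = list(expr.index)

    collections = {
        "pathway": GeneSetCollection(io.read_gmt(DATA / "synthetic_pathways.gmt"),
                                     source="pathway"),
        "tf": GeneSetCollection(io.read_gmt(DATA / "synthetic_tf_targets.gmt"),
                                source="tf_targets"),
        "mirna": GeneSetCollection(io.read_gmt(DATA / "synthetic_mirna_targets.gmt"),
                                   source="mirna_targets"),
    }

    frames = []
    for m in significant:
        query = list(labels.index[labels == m])
        for key, coll in collections.items():
            res = hypergeom_ora(query, coll, universe)
            res.insert(0, "module", m)
            frames.append(res)
    enrichment = (pd.concat(frames, ignore_index=True)
                  if frames else pd.DataFrame(columns=["module", "set", "source"]))
    enrichment.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    print(f"enriched sets (adjusted p <= 0.05, size >= 5): {len(enrichment)}")
    if not enrichment.empty:
        print(enrichment[["module", "set", "source", "overlap", "set_size",
                          "p.adj"]].round(6).to_string(index=False))

    # key genes: top intramodular hubs by |MM| per significant module
    key_frames = []
    for m in significant:
        sub = gene_stats[gene_stats["module"] == m].copy()
        sub["absMM"] = sub["MM"].abs()
        key_frames.append(sub.sort_values("absMM", ascending=False).head(10))
    key_genes = pd.concat(key_frames) if key_frames else pd.DataFrame()

    enriched_tfs = list(enrichment.loc[enrichment["source"] == "tf_targets", "set"])
    enriched_mirnas = list(enrichment.loc[enrichment["source"] == "mirna_targets", "set"])
    graph = build_regnet(key_genes, tf_sets=collections["tf"],
                         mirna_sets=collections["mirna"],
                         enriched_tfs=enriched_tfs, enriched_mirnas=enriched_mirnas)
    io.write_graphml(graph, OUT / "regnet.graphml")
    io.write_sif(graph, OUT / "regnet.sif")
    print(f"regulatory network: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges "
          f"({len(enriched_tfs)} TFs, {len(enriched_mirnas)} miRNAs)")


if __name__ == "__main__":
    main()
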