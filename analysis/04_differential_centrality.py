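"""Differential betweenness centrality within trait-significant modules.

Rebuilds case and control TOM networks (shared soft threshold) for each
module that passed the trait-association screen, computes weighted
betweenness with inverse-TOM edge lengths, and ranks genes by the absolute
change in betweenness between conditions — the coordinator-candidate
ranking. Writes results/centrality.tsv.
"""

from pathlib import Path

import pandas as pd

from coexnet import centrality as cent
from coexnet import io

PRE = Path("results/preprocessed")
NET = Path("results/network")
OUT = Path("results")


def main() -> None:
    expr = io.read_expression(PRE / "expr_adjusted.tsv")
    metadata = io.read_metadata(PRE / "metadata.tsv")
    labels = pd.read_csv(NET / "modules.tsv", sep="\t", index_col=0)["module"]
    summary = io.read_json(NET / "summary.json")
    beta = summary["chosen_beta"]
    significant = summary["significant_modules"]
    print(f"modules entering centrality analysis: {significant} (beta = {beta})")

    tables = []
    for m in significant:
        genes = list(labels.index[labels == m])
        nets = cent.condition_networks(expr, metadata, genes, beta=beta, module_id=m)
        bc_case = cent.betweenness(nets.tom_case)
        bc_control = cent.betweenness(nets.tom_control)
        table = cent.differential_bc(bc_case, bc_control, module_id=m)
        tables.append(table)
        top = table.head(5)
        print(f"\nmodule {m} ({len(genes)} genes), top |delta BC|:")
        print(top[["BC_case", "BC_control", "delta"]].round(1).to_string())

    if tables:
        pd.concat(tables).to_csv(OUT / "centrality.tsv", sep="\t", index_label="gene")
        print(f"\nwrote {OUT / 'centrality.tsv'}")
    else:
        print("no trait-significant modules; nothing to rank")


if __name__ == "__main__":
    main()
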