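"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV with genes on rows (first column ``gene_id``,
header row of sample ids); sample metadata as TSV with a ``sample_id`` column;
gene-set collections as GMT; regulatory networks as GraphML and SIF.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

METADATA_COLUMNS = ["sample_id", "trait", "sex", "age", "race", "bmi", "ischemic_time"]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV into a DataFrame (genes on rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample ids in expression matrix")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; ``sample_id`` becomes the index, trait must be 0/1."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "trait" not in meta.columns:
        raise ValueError("metadata requires sample_id and trait columns")
    meta = meta.set_index("sample_id")
    if not set(meta["trait"].unique()) <= {0, 1}:
        raise ValueError("trait must be binary 0/1")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (set name, description, member genes)."""
    from gseapy.parser import read_gmt as _read_gmt  # slow import, keep lazy

    return _read_gmt(str(path))


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(genes) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_sif(graph: nx.DiGraph, path: str | Path) -> Path:
    """Write a directed network in Cytoscape SIF (source, interaction, target)."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get('evidence', 'interaction')}\t{v}\n")
        for node in sorted(graph.nodes):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")
    return path


def write_graphml(graph: nx.DiGraph, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)
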