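"""End-to-end orchestration of the co-expression analysis.

Runs the full sequence — cohort matching, gene filtering, log transform,
surrogate-variable adjustment, sample-network outlier removal, soft-threshold
selection, TOM, module detection, eigengene/trait statistics, differential
betweenness centrality on trait-significant modules, and (when collections
are supplied) over-representation analysis plus the regulatory network —
writing every stage's tables and a run manifest under an output directory.
Deterministic given the config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import centrality as cent
from . import enrichment as enr
from . import io
from . import modules as mod
from . import network as net
from . import preprocess as pp
from . import sample_qc as qc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run."""

    counts: str = ""
    tpm: str = ""
    metadata: str = ""
    out_dir: str = "coexnet_run"
    pathway_gmt: str | None = None
    tf_gmt: str | None = None
    mirna_gmt: str | None = None
    extra_edges: str | None = None

    ratio: int = 2
    match_covariates: tuple[str, ...] = ("sex", "age", "race")
    low_count: float = 10.0
    low_prop: float = 0.9
    mad_keep: float = 0.5
    known_covariates: tuple[str, ...] = ("sex", "age", "bmi", "ischemic_time")
    n_sv: int = 3
    zk_cutoff: float = -2.5
    beta_min: int = 1
    beta_max: int = 20
    r2_cut: float = 0.85
    n_bins: int = 10
    min_module_size: int = 30
    cut_height_quantile: float = 0.5
    module_trait_alpha: float = 0.05
    ora_alpha: float = 0.05
    ora_min_size: int = 5
    n_hub_genes: int = 10
    seed: int = 0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        blob = dataclasses.asdict(self)
        for key in ("match_covariates", "known_covariates"):
            blob[key] = list(blob[key])
        path.write_text(yaml.safe_dump(blob, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        blob = yaml.safe_load(Path(path).read_text())
        for key in ("match_covariates", "known_covariates"):
            if key in blob:
                blob[key] = tuple(blob[key])
        return cls(**blob)


def _write_table(df: pd.DataFrame, path: Path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": dataclasses.asdict(config), "stages": {}}
    for key in ("match_covariates", "known_covariates"):
        manifest["parameters"][key] = list(manifest["parameters"][key])

    counts = io.read_expression(config.counts)
    tpm = io.read_expression(config.tpm)
    metadata = io.read_metadata(config.metadata)

    # 1. cohort matching
    match = pp.match_cohort(metadata, ratio=config.ratio,
                            match_covariates=list(config.match_covariates))
    retained = match.retained_sample_ids
    counts, tpm = counts[retained], tpm[retained]
    metadata_m = metadata.loc[retained]
    match.balance_report.to_csv(out / "balance_report.tsv", sep="\t", index_label="covariate")
    manifest["stages"]["match"] = {
        "n_cases": len(match.case_ids),
        "n_controls": len(match.control_ids),
        "total_distance": match.total_distance,
    }

    # 2. gene filters + log transform
    filtered = pp.filter_genes(counts, tpm, metadata_m, low_count=config.low_count,
                               low_prop=config.low_prop, mad_keep=config.mad_keep)
    logtpm = pp.log_transform(filtered)
    manifest["stages"]["filter"] = {"n_genes_in": len(counts), "n_genes_out": len(filtered)}

    # 3. sample-network outlier removal (on logTPM, before adjustment: the
    # residual-PCA correction would otherwise absorb single-sample aberrations)
    reports = qc.detect_outliers(logtpm, metadata_m, cutoff=config.zk_cutoff)
    qc_frame = pd.concat([r.to_frame() for r in reports.values()])
    _write_table(qc_frame, out / "sample_qc.tsv", index_label="sample_id")
    outliers = sorted(set().union(*(r.flagged_outliers for r in reports.values())))
    keep = [s for s in logtpm.columns if s not in outliers]
    metadata_f = metadata_m.loc[keep]
    manifest["stages"]["qc"] = {
        "outliers": outliers,
        "n_samples_out": len(keep),
        "outliers_per_group": {g: len(r.flagged_outliers) for g, r in reports.items()},
    }

    # 4. surrogate-variable adjustment
    adj = pp.estimate_and_remove_surrogates(logtpm[keep], metadata_f,
                                            known_covariates=list(config.known_covariates),
                                            n_sv=config.n_sv)
    _write_table(adj.sv_matrix, out / "surrogate_variables.tsv", index_label="sv")
    expr = adj.adjusted
    manifest["stages"]["adjust"] = {"n_sv": adj.n_sv}

    # 5. network: soft threshold, adjacency, TOM
    sim = net.similarity(expr)
    fit = net.pick_soft_threshold(sim, beta_grid=range(config.beta_min, config.beta_max + 1),
                                  r2_cut=config.r2_cut, n_bins=config.n_bins)
    _write_table(fit.to_frame(), out / "soft_threshold.tsv")
    tom = net.topological_overlap(net.adjacency(sim, fit.chosen_beta))
    manifest["stages"]["network"] = {
        "chosen_beta": fit.chosen_beta,
        "signed_r2": fit.signed_r2[fit.chosen_beta],
        "n_genes": len(expr),
    }

    # 6. module detection + eigengenes + trait statistics
    assignment = mod.detect_modules(net.diss_tom(tom), min_module_size=config.min_module_size,
                                    cut_height_quantile=config.cut_height_quantile)
    me = mod.module_eigengenes(expr, assignment)
    stats = mod.module_trait_stats(expr, me, metadata_f, assignment)
    assignment.labels.to_frame("module").to_csv(out / "modules.tsv", sep="\t",
                                                index_label="gene")
    _write_table(me.me, out / "eigengenes.tsv", index_label="module")
    _write_table(stats.module_trait, out / "module_trait.tsv")
    _write_table(stats.gene_stats, out / "gene_stats.tsv", index_label="gene")
    sizes = assignment.labels.value_counts().to_dict()
    manifest["stages"]["modules"] = {
        "n_modules": len(assignment.module_ids),
        "module_sizes": {m: int(sizes[m]) for m in assignment.module_ids},
        "n_unassigned": int(sizes.get(mod.UNASSIGNED, 0)),
    }

    # 7. differential betweenness centrality on trait-significant modules
    significant = stats.significant_modules(config.module_trait_alpha)
    cent_tables = []
    for m in significant:
        nets = cent.condition_networks(expr, metadata_f, assignment.genes_in(m),
                                       beta=fit.chosen_beta, module_id=m)
        bc_case = cent.betweenness(nets.tom_case)
        bc_control = cent.betweenness(nets.tom_control)
        cent_tables.append(cent.differential_bc(bc_case, bc_control, module_id=m))
    if cent_tables:
        centrality_table = pd.concat(cent_tables)
        _write_table(centrality_table, out / "centrality.tsv", index_label="gene")
    else:
        centrality_table = pd.DataFrame()
    manifest["stages"]["centrality"] = {"modules": significant}

    # 8. enrichment + regulatory network (optional inputs)
    universe = list(expr.index)
    enrich_frames = []
    collections = {
        "pathway": (config.pathway_gmt, "pathway"),
        "tf": (config.tf_gmt, "tf_targets"),
        "mirna": (config.mirna_gmt, "mirna_targets"),
    }
    loaded: dict[str, enr.GeneSetCollection] = {}
    for key, (path, source) in collections.items():
        if path:
            loaded[key] = enr.GeneSetCollection(io.read_gmt(path), source=source)
    for m in significant:
        query = assignment.genes_in(m)
        for key, coll in loaded.items():
            res = enr.hypergeom_ora(query, coll, universe, min_size=config.ora_min_size,
                                    alpha=config.ora_alpha)
            res.insert(0, "module", m)
            enrich_frames.append(res)
    if enrich_frames:
        enrichment_table = pd.concat(enrich_frames, ignore_index=True)
        _write_table(enrichment_table, out / "enrichment.tsv")
    else:
        enrichment_table = pd.DataFrame()
    manifest["stages"]["enrichment"] = {
        "collections": sorted(loaded),
        "n_enriched": int(len(enrichment_table)),
    }

    if loaded and significant:
        key_genes = pd.concat(
            [mod.hub_genes(stats, m, top=config.n_hub_genes) for m in significant]
        )
        if not centrality_table.empty:
            top_bc = centrality_table.sort_values("delta", key=abs, ascending=False)
            key_genes = pd.concat([key_genes, stats.gene_stats.loc[
                [g for g in top_bc.index[: config.n_hub_genes] if g not in key_genes.index]
            ]])
        enriched = {
            key: list(enrichment_table[enrichment_table["source"] == coll.source]["set"].unique())
            for key, coll in loaded.items()
        } if not enrichment_table.empty else {key: [] for key in loaded}
        extra = pd.read_csv(config.extra_edges, sep="\t") if config.extra_edges else None
        graph = enr.build_regnet(
            key_genes,
            tf_sets=loaded.get("tf"),
            mirna_sets=loaded.get("mirna"),
            enriched_tfs=enriched.get("tf"),
            enriched_mirnas=enriched.get("mirna"),
            extra_edges=extra,
        )
        io.write_graphml(graph, out / "regnet.graphml")
        io.write_sif(graph, out / "regnet.sif")
        manifest["stages"]["regnet"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
        }

    io.write_json(manifest, out / "manifest.json")
    return manifest
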