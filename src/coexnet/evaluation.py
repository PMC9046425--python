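"""Recovery experiments on planted synthetic data.

Each function runs one self-contained experiment of the validation study —
cohort-matching arithmetic, module recovery, outlier recovery, surrogate
recovery, differential-betweenness recovery — by generating a synthetic
cohort with known ground truth and pushing it through the corresponding
pipeline stages. Shared by the test suite, the analysis drivers, and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import centrality as cent
from . import modules as mod
from . import network as net
from . import preprocess as pp
from . import sample_qc as qc
from .simulate import (
    SimulationConfig,
    simulate_bridge_condition,
    simulate_dataset,
    simulate_metadata,
)

__all__ = [
    "matching_arithmetic",
    "ModuleRecovery",
    "module_recovery",
    "outlier_recovery",
    "surrogate_recovery",
    "bridge_bc_recovery",
]


def matching_arithmetic(n_cases: int = 75, n_controls: int = 256, ratio: int = 2,
                        seed: int = 0) -> int:
    """Number of controls retained by ratio-matching a synthetic cohort."""
    meta = simulate_metadata(n_cases, n_controls, seed=seed)
    result = pp.match_cohort(meta, ratio=ratio)
    return len(result.control_ids)


@dataclass
class ModuleRecovery:
    """Outcome of one module-recovery run against planted labels."""

    ari: float
    chosen_beta: int
    n_modules: int
    trait_module_is_top: bool
    trait_module_p: float


def module_recovery(seed: int, config: SimulationConfig | None = None,
                    n_sv: int = 3) -> ModuleRecovery:
    """Detect modules on one planted cohort and score against ground truth.

    The analysis path mirrors the pipeline: log2(TPM+1), surrogate-variable
    adjustment, soft-threshold selection, TOM, static-cut module detection,
    eigengene-trait statistics. ARI is computed over genes assigned on both
    sides (planted background and detected sink excluded).
    """
    if config is None:
        config = SimulationConfig(seed=seed, n_outliers=0)
    _, tpm, meta, truth = simulate_dataset(config)
    adj = pp.estimate_and_remove_surrogates(pp.log_transform(tpm), meta, n_sv=n_sv)
    sim = net.similarity(adj.adjusted)
    fit = net.pick_soft_threshold(sim)
    tom = net.topological_overlap(net.adjacency(sim, fit.chosen_beta))
    assignment = mod.detect_modules(net.diss_tom(tom))
    true_labels = pd.Series(truth.gene_module_labels)

    mask = (true_labels != mod.UNASSIGNED) & (assignment.labels != mod.UNASSIGNED)
    ari = float(adjusted_rand_score(true_labels[mask], assignment.labels[mask]))

    me = mod.module_eigengenes(adj.adjusted, assignment)
    stats = mod.module_trait_stats(adj.adjusted, me, meta, assignment)
    trait_idx = int(np.argmax(np.abs(config.eigengene_trait_cor)))
    planted_id = f"M{trait_idx + 1}"
    in_modules = assignment.labels[true_labels == planted_id].value_counts()
    detected = next((m for m in in_modules.index if m != mod.UNASSIGNED), None)
    mt = stats.module_trait.set_index("module")
    top_module = mt["cor"].abs().idxmax()
    return ModuleRecovery(
        ari=ari,
        chosen_beta=fit.chosen_beta,
        n_modules=len(assignment.module_ids),
        trait_module_is_top=bool(detected is not None and top_module == detected),
        trait_module_p=float(mt.loc[top_module, "p"]),
    )


def outlier_recovery(seed: int, shift: float = 3.0, n_outliers: int = 2,
                     cutoff: float = -2.5) -> tuple[int, int, int]:
    """(planted, correctly flagged, falsely flagged) for one cohort."""
    config = SimulationConfig(seed=seed, n_outliers=n_outliers, outlier_shift=shift)
    _, tpm, meta, truth = simulate_dataset(config)
    reports = qc.detect_outliers(pp.log_transform(tpm), meta, cutoff=cutoff)
    flagged = set().union(*(set(r.flagged_outliers) for r in reports.values()))
    planted = set(truth.outlier_sample_ids)
    return len(planted), len(flagged & planted), len(flagged - planted)


def canonical_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Canonical correlations between column spaces of x and y (samples x k)."""
    qx, _ = np.linalg.qr(x - x.mean(axis=0))
    qy, _ = np.linalg.qr(y - y.mean(axis=0))
    return np.linalg.svd(qx.T @ qy, compute_uv=False)


def surrogate_recovery(seed: int, n_sv: int = 2, strength: float = 1.0) -> float:
    """First canonical correlation between estimated SVs and planted components."""
    config = SimulationConfig(seed=seed, n_outliers=0, n_surrogates=n_sv,
                              surrogate_strength=strength)
    _, tpm, meta, truth = simulate_dataset(config)
    adj = pp.estimate_and_remove_surrogates(pp.log_transform(tpm), meta, n_sv=n_sv)
    cc = canonical_correlations(adj.sv_matrix.to_numpy().T,
                                truth.surrogate_matrix.to_numpy().T)
    return float(cc[0])


def bridge_bc_recovery(seed: int, beta: float = 6.0) -> tuple[bool, pd.DataFrame]:
    """Whether the planted case-only bridge gene tops |delta BC|."""
    expr, meta, bridge = simulate_bridge_condition(seed=seed)
    nets = cent.condition_networks(expr, meta, list(expr.index), beta=beta,
                                   module_id="bridge_fixture")
    table = cent.differential_bc(cent.betweenness(nets.tom_case),
                                 cent.betweenness(nets.tom_control),
                                 module_id="bridge_fixture")
    return bool(table.index[0] == bridge), table
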