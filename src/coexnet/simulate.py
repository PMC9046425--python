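"""Synthetic expression cohorts with planted co-expression structure.

The generator produces a genes x samples cohort from a latent factor model so
that every downstream stage of the pipeline has ground truth to recover:

* each planted module m is driven by a latent eigengene ``E_m`` (one factor per
  module), built as a mixture of the standardized binary trait and Gaussian
  noise so that cor(E_m, trait) hits a configured target exactly in
  expectation;
* every gene loads on its module eigengene with a loading calibrated to reach
  a configured gene-eigengene correlation, plus hidden surrogate components
  (batch-like noise shared across all genes) and independent Gaussian noise;
* background genes carry only surrogate + noise signal;
* a configurable number of samples is displaced by a multiple of the median
  inter-sample distance to plant detectable outliers;
* the latent log-scale matrix is exponentiated and normalized per sample to a
  constant column sum to give TPM, and read counts are Poisson draws around
  TPM scaled by a library-size factor.

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_dataset",
    "write_fixture",
    "read_fixture",
    "scale_free_similarity",
]

UNASSIGNED = "unassigned"


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure generator.

    Defaults mirror a desk-scale cohort: ~880 genes, 22 cases vs 44 controls,
    three planted modules, one of which is coupled to the trait at r = 0.4.
    """

    n_genes: int = 880
    n_cases: int = 22
    n_controls: int = 44
    module_sizes: tuple[int, ...] = (80, 60, 40)
    eigengene_trait_cor: tuple[float, ...] = (0.4, 0.0, 0.0)
    within_module_cor: tuple[float, ...] = (0.8, 0.8, 0.8)
    n_surrogates: int = 3
    surrogate_strength: float = 0.6
    anti_correlated_fraction: float = 0.3
    n_outliers: int = 2
    outlier_shift: float = 4.0
    noise_sd: float = 0.6
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 0.8
    low_expression_fraction: float = 0.05
    library_size: float = 2e6
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes exceed n_genes")
        if len(self.eigengene_trait_cor) != self.n_modules:
            raise ValueError("eigengene_trait_cor length must match module_sizes")
        if len(self.within_module_cor) != self.n_modules:
            raise ValueError("within_module_cor length must match module_sizes")
        for lam in self.eigengene_trait_cor:
            if not -1.0 <= lam <= 1.0:
                raise ValueError("eigengene_trait_cor must lie in [-1, 1]")
        for rho in self.within_module_cor:
            if not 0.0 < rho < 1.0:
                raise ValueError("within_module_cor must lie in (0, 1)")
        if self.noise_sd < 0 or self.surrogate_strength < 0 or self.outlier_shift < 0:
            raise ValueError("noise_sd, surrogate_strength, outlier_shift must be >= 0")
        if self.n_outliers > self.n_samples:
            raise ValueError("more outliers than samples")
        vals = [self.noise_sd, self.surrogate_strength, self.outlier_shift,
                self.baseline_log2_mean, self.baseline_log2_sd, self.library_size,
                *self.eigengene_trait_cor, *self.within_module_cor]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite configuration value")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated cohort."""

    gene_module_labels: dict[str, str]  # gene id -> module id or "unassigned"
    outlier_sample_ids: list[str]
    eigengene_matrix: pd.DataFrame  # modules x samples
    trait_vector: pd.Series  # sample -> 0/1
    surrogate_matrix: pd.DataFrame  # components x samples
    config: SimulationConfig


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def simulate_dataset(config: SimulationConfig):
    """Generate (counts, tpm, metadata, truth) for one synthetic cohort.

    Returns DataFrames shaped genes x samples for counts and TPM, a metadata
    frame indexed by sample id, and a :class:`SyntheticTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = config.n_genes, config.n_samples

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    trait = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)]).astype(int)
    t_std = _standardize(trait.astype(float))

    # latent eigengenes: exact trait coupling in expectation
    eigengenes = np.empty((config.n_modules, n_samples))
    for m, lam in enumerate(config.eigengene_trait_cor):
        z = rng.standard_normal(n_samples)
        eigengenes[m] = lam * t_std + np.sqrt(1.0 - lam**2) * z

    surrogates = rng.standard_normal((max(config.n_surrogates, 0), n_samples))

    labels = np.full(n_genes, UNASSIGNED, dtype=object)
    latent = np.empty((n_genes, n_samples))
    sigma_other = float(np.hypot(config.surrogate_strength, config.noise_sd))
    for g in range(n_genes):
        if config.n_surrogates > 0:
            w = rng.standard_normal(config.n_surrogates)
            w /= np.linalg.norm(w)
            sur = config.surrogate_strength * (w @ surrogates)
        else:
            sur = 0.0
        latent[g] = sur + config.noise_sd * rng.standard_normal(n_samples)

    start = 0
    for m, size in enumerate(config.module_sizes):
        rho = config.within_module_cor[m]
        # loading calibrated so |cor(gene, eigengene)| = rho given the noise
        # level; a fraction of genes loads negatively, as in unsigned networks
        b = rho * sigma_other / np.sqrt(1.0 - rho**2)
        for g in range(start, start + size):
            sign = -1.0 if rng.uniform() < config.anti_correlated_fraction else 1.0
            latent[g] = sign * b * eigengenes[m] + latent[g]
            labels[g] = f"M{m + 1}"
        start += size

    baselines = config.baseline_log2_mean + config.baseline_log2_sd * rng.standard_normal(n_genes)
    # a slice of background genes is pushed to near-zero expression so the
    # low-count filter has genuine work to do
    n_low = int(round(config.low_expression_fraction * (n_genes - start)))
    if n_low > 0:
        low_idx = rng.choice(np.arange(start, n_genes), size=n_low, replace=False)
        baselines[low_idx] -= 12.0

    log_expr = baselines[:, None] + latent

    # plant outliers: displace whole samples by a multiple of the median
    # inter-sample distance along a random direction in gene space
    outlier_ids: list[str] = []
    if config.n_outliers > 0 and config.outlier_shift > 0:
        from scipy.spatial.distance import pdist

        med = float(np.median(pdist(log_expr.T)))
        # outliers alternate between the trait groups (controls first), as
        # aberrant samples occur in both arms of a cohort
        control_pool = list(rng.permutation(np.flatnonzero(trait == 0)))
        case_pool = list(rng.permutation(np.flatnonzero(trait == 1)))
        out_idx = []
        for i in range(config.n_outliers):
            pool = control_pool if (i % 2 == 0 and control_pool) or not case_pool else case_pool
            out_idx.append(pool.pop())
        for s in np.sort(out_idx):
            direction = rng.standard_normal(n_genes)
            direction /= np.linalg.norm(direction)
            log_expr[:, s] += config.outlier_shift * med * direction
            outlier_ids.append(sample_ids[s])

    raw = np.exp2(log_expr)
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    counts = rng.poisson(tpm * (config.library_size / 1e6)).astype(np.int64)

    metadata = _covariate_frame(rng, trait, sample_ids)

    gene_index = pd.Index(gene_ids, name="gene_id")
    counts_df = pd.DataFrame(counts, index=gene_index, columns=sample_ids)
    tpm_df = pd.DataFrame(tpm, index=gene_index, columns=sample_ids)
    truth = SyntheticTruth(
        gene_module_labels=dict(zip(gene_ids, labels)),
        outlier_sample_ids=outlier_ids,
        eigengene_matrix=pd.DataFrame(
            eigengenes, index=[f"M{m + 1}" for m in range(config.n_modules)], columns=sample_ids
        ),
        trait_vector=pd.Series(trait, index=sample_ids, name="trait"),
        surrogate_matrix=pd.DataFrame(
            surrogates,
            index=[f"SV{i + 1}" for i in range(config.n_surrogates)],
            columns=sample_ids,
        ),
        config=config,
    )
    return counts_df, tpm_df, metadata, truth


def _covariate_frame(rng: np.random.Generator, trait: np.ndarray,
                     sample_ids: list[str]) -> pd.DataFrame:
    """Demographic covariates with mild trait shifts (older, heavier cases)."""
    n = len(trait)
    return pd.DataFrame(
        {
            "trait": trait,
            "sex": rng.integers(0, 2, n),
            "age": np.round(rng.normal(55.0, 12.0, n) + 4.0 * trait, 1),
            "race": rng.choice([0, 1, 2], size=n, p=[0.7, 0.2, 0.1]),
            "bmi": np.round(rng.normal(27.0, 4.0, n) + 2.0 * trait, 2),
            "ischemic_time": np.round(rng.normal(600.0, 180.0, n), 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def simulate_metadata(n_cases: int, n_controls: int, seed: int = 0) -> pd.DataFrame:
    """Sample metadata alone, for cohort-matching experiments at any size."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    trait = np.concatenate([np.ones(n_cases), np.zeros(n_controls)]).astype(int)
    return _covariate_frame(rng, trait, [f"S{i:04d}" for i in range(n)])


def simulate_bridge_condition(n_block: int = 8, n_per_group: int = 60,
                              factor_cor: float = 0.5, block_cor: float = 0.3,
                              bridge_cor: float = 0.98, seed: int = 0):
    """Two-condition fixture where one gene bridges two sub-blocks only in cases.

    A module consists of two gene blocks driven by latent factors that share a
    weak common component (cor = ``block_cor``); block genes couple to their
    factor at ``factor_cor``, loosely enough that two hops through a strong
    hub are shorter than a direct edge in the inverse-TOM metric. The
    designated bridge gene tracks the average of both factors almost
    noiselessly in case samples — so both within- and cross-block shortest
    paths route through it — but is pure noise in controls, where cross-block
    traffic scatters over many mediocre direct edges. Its betweenness
    therefore collapses between the condition networks. The latent factors
    are built on an exactly orthonormal basis within each trait group so the
    planted geometry is not distorted by subsampling. Returns
    (expr, metadata, bridge_gene).
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    trait = np.concatenate([np.ones(n_per_group), np.zeros(n_per_group)]).astype(int)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    fa = np.empty(n_samples)
    fb = np.empty(n_samples)
    comb = np.empty(n_samples)
    for mask in (trait == 1, trait == 0):
        m = int(mask.sum())
        raw = rng.standard_normal((m, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        shared, ea, eb = (q[:, i] * np.sqrt(m) for i in range(3))
        fa[mask] = np.sqrt(block_cor) * shared + np.sqrt(1 - block_cor) * ea
        fb[mask] = np.sqrt(block_cor) * shared + np.sqrt(1 - block_cor) * eb
        comb[mask] = (fa[mask] + fb[mask]) / np.sqrt(2 * (1 + block_cor))

    rows, gene_ids = [], []
    noise = np.sqrt(1.0 - factor_cor**2)
    for name, factor in (("A", fa), ("B", fb)):
        for i in range(n_block):
            rows.append(factor_cor * factor + noise * rng.standard_normal(n_samples))
            gene_ids.append(f"{name}{i:02d}")
    bridge = np.sqrt(1.0 - bridge_cor**2) * rng.standard_normal(n_samples)
    case = trait == 1
    bridge[case] = (bridge_cor * comb[case]
                    + np.sqrt(1.0 - bridge_cor**2) * rng.standard_normal(int(case.sum())))
    rows.append(bridge)
    gene_ids.append("BRIDGE")

    expr = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    metadata = _covariate_frame(rng, trait, sample_ids)
    return expr, metadata, "BRIDGE"


def write_fixture(dataset, directory: str | Path) -> dict[str, Path]:
    """Persist a simulated cohort as counts.tsv / tpm.tsv / metadata.tsv / truth.json."""
    counts, tpm, metadata, truth = dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": io.write_expression(counts, directory / "counts.tsv"),
        "tpm": io.write_expression(tpm, directory / "tpm.tsv"),
        "metadata": io.write_metadata(metadata, directory / "metadata.tsv"),
    }
    cfg = asdict(truth.config)
    cfg["module_sizes"] = list(cfg["module_sizes"])
    cfg["eigengene_trait_cor"] = list(cfg["eigengene_trait_cor"])
    cfg["within_module_cor"] = list(cfg["within_module_cor"])
    paths["truth"] = io.write_json(
        {
            "gene_module_labels": truth.gene_module_labels,
            "outlier_sample_ids": truth.outlier_sample_ids,
            "eigengene_matrix": truth.eigengene_matrix.to_dict(orient="split"),
            "trait_vector": truth.trait_vector.to_dict(),
            "surrogate_matrix": truth.surrogate_matrix.to_dict(orient="split"),
            "config": cfg,
        },
        directory / "truth.json",
    )
    return paths


def read_fixture(directory: str | Path):
    """Load a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    counts = io.read_expression(directory / "counts.tsv")
    tpm = io.read_expression(directory / "tpm.tsv")
    metadata = io.read_metadata(directory / "metadata.tsv")
    blob = io.read_json(directory / "truth.json")
    cfg = dict(blob["config"])
    cfg["module_sizes"] = tuple(cfg["module_sizes"])
    cfg["eigengene_trait_cor"] = tuple(cfg["eigengene_trait_cor"])
    cfg["within_module_cor"] = tuple(cfg["within_module_cor"])
    em = blob["eigengene_matrix"]
    sm = blob["surrogate_matrix"]
    truth = SyntheticTruth(
        gene_module_labels=blob["gene_module_labels"],
        outlier_sample_ids=list(blob["outlier_sample_ids"]),
        eigengene_matrix=pd.DataFrame(em["data"], index=em["index"], columns=em["columns"]),
        trait_vector=pd.Series(blob["trait_vector"], name="trait"),
        surrogate_matrix=pd.DataFrame(sm["data"], index=sm["index"], columns=sm["columns"]),
        config=SimulationConfig(**cfg),
    )
    return counts, tpm, metadata, truth


def scale_free_similarity(n_genes: int = 300, gamma: float = 2.5, k_min: float = 2.0,
                          seed: int = 0) -> np.ndarray:
    """Similarity matrix whose connectivity follows an exact power-law tail.

    Uses a Chung-Lu expected-degree construction: draw degrees from a Pareto
    law with exponent ``gamma`` and set s_ij proportional to k_i * k_j so that
    the row sums reproduce the drawn degree sequence. Used to exercise the
    scale-free model-fit criterion at beta = 1.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n_genes)
    k = k_min * (1.0 - u) ** (-1.0 / (gamma - 1.0))
    s = np.outer(k, k) / k.sum()
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s
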