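"""Cohort matching and expression preprocessing.

Stages, in pipeline order: optimal propensity-score matching of controls to
cases at a fixed ratio; removal of genes lowly expressed in both trait groups
followed by a median-absolute-deviation variability filter; log2(x + 1)
transform of TPM; and adjustment for hidden confounders by regressing out
principal components of the covariate-residual matrix (a residual-PCA
estimate of surrogate variables).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import median_abs_deviation

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "SurrogateAdjustment",
    "match_cohort",
    "filter_genes",
    "log_transform",
    "estimate_and_remove_surrogates",
]


@dataclass
class MatchResult:
    """Outcome of ratio-matching controls to cases on a propensity score."""

    retained_sample_ids: list[str]
    case_ids: list[str]
    control_ids: list[str]
    match_map: dict[str, list[str]]
    balance_report: pd.DataFrame  # per covariate: SMD before/after
    total_distance: float


@dataclass
class SurrogateAdjustment:
    """Estimated surrogate variables and the adjusted expression matrix."""

    n_sv: int
    sv_matrix: pd.DataFrame  # components x samples, orthonormal rows
    adjusted: pd.DataFrame  # genes x samples


def _design_matrix(meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design from metadata columns; categoricals one-hot encoded."""
    cols = {}
    for cov in covariates:
        col = meta[cov]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].astype(float)
        else:
            cols[cov] = col.astype(float)
    return pd.DataFrame(cols, index=meta.index)


def _smd(x: pd.Series, case_mask: np.ndarray, control_mask: np.ndarray) -> float:
    """Standardized mean difference between groups (pooled-SD denominator)."""
    a, b = x[case_mask], x[control_mask]
    pooled = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def match_cohort(metadata: pd.DataFrame, ratio: int = 2,
                 match_covariates: list[str] | None = None) -> MatchResult:
    """Match each case to exactly ``ratio`` controls by optimal assignment.

    A propensity score is fitted by logistic regression of the trait on the
    covariates; each case is replicated ``ratio`` times and a globally optimal
    (minimum total distance) rectangular assignment is solved over the
    case-replicate x control matrix of absolute differences on the
    linear-predictor (logit) scale. Distance ties are broken by sample-id
    order through the deterministic assignment solver.
    """
    from sklearn.linear_model import LogisticRegression

    if match_covariates is None:
        match_covariates = ["sex", "age", "race"]
    meta = metadata.sort_index()
    trait = meta["trait"].to_numpy()
    case_ids = list(meta.index[trait == 1])
    control_ids_all = list(meta.index[trait == 0])
    if ratio * len(case_ids) > len(control_ids_all):
        raise ValueError(
            f"insufficient controls: need {ratio * len(case_ids)}, have {len(control_ids_all)}"
        )

    design = _design_matrix(meta, match_covariates)
    keep = []
    for col in design.columns:
        if design[col].nunique() <= 1:
            warnings.warn(f"covariate {col!r} is constant; dropped from matching")
        else:
            keep.append(col)
    if not keep:
        raise ValueError("no usable matching covariates")
    X = design[keep].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
    model.fit(X, trait)
    logit = X @ model.coef_.ravel() + model.intercept_[0]

    case_mask = trait == 1
    control_mask = ~case_mask
    cost = np.abs(logit[case_mask][:, None] - logit[control_mask][None, :])
    cost_rep = np.repeat(cost, ratio, axis=0)  # each case duplicated `ratio` times
    rows, cols = linear_sum_assignment(cost_rep)

    match_map: dict[str, list[str]] = {cid: [] for cid in case_ids}
    for r, c in zip(rows, cols):
        match_map[case_ids[r // ratio]].append(control_ids_all[c])
    for cid in match_map:
        match_map[cid].sort()
    matched_controls = sorted({c for ctrls in match_map.values() for c in ctrls})
    retained = sorted(case_ids) + matched_controls

    after_mask = meta.index.isin(retained)
    report = pd.DataFrame(
        {
            "smd_before": [_smd(design[c], case_mask, control_mask) for c in design.columns],
            "smd_after": [
                _smd(design[c], case_mask & after_mask, control_mask & after_mask)
                for c in design.columns
            ],
        },
        index=design.columns,
    )
    logger.info("matched %d cases to %d controls (ratio %d)", len(case_ids),
                len(matched_controls), ratio)
    return MatchResult(
        retained_sample_ids=retained,
        case_ids=sorted(case_ids),
        control_ids=matched_controls,
        match_map=match_map,
        balance_report=report,
        total_distance=float(cost_rep[rows, cols].sum()),
    )


def filter_genes(counts: pd.DataFrame, tpm: pd.DataFrame, metadata: pd.DataFrame,
                 low_count: float = 10, low_prop: float = 0.9,
                 mad_keep: float = 0.5) -> pd.DataFrame:
    """Drop genes lowly expressed in both groups, then keep the top-MAD half.

    A gene is removed iff, in *both* trait groups, the fraction of samples
    with count < ``low_count`` exceeds ``low_prop`` (kept when adequately
    expressed in either group). Of the survivors, the ceil(mad_keep * n) genes
    with the largest median absolute deviation of TPM across all samples are
    retained, in this fixed order.
    """
    if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and tpm must share gene and sample ids")
    samples = counts.columns
    trait = metadata.loc[samples, "trait"].to_numpy()
    if (trait == 1).sum() == 0 or (trait == 0).sum() == 0:
        raise ValueError("both trait groups must be nonempty")

    low = counts.to_numpy() < low_count
    frac_case = low[:, trait == 1].mean(axis=1)
    frac_control = low[:, trait == 0].mean(axis=1)
    drop = (frac_case > low_prop) & (frac_control > low_prop)
    survivors = counts.index[~drop]
    if len(survivors) == 0:
        raise ValueError("all genes removed by the low-count filter")
    logger.info("low-count filter: %d -> %d genes", len(counts), len(survivors))

    tpm_surv = tpm.loc[survivors]
    mad = pd.Series(
        median_abs_deviation(tpm_surv.to_numpy(), axis=1, scale=1.0), index=survivors
    )
    n_keep = math.ceil(mad_keep * len(survivors))
    # stable order: sort by (-MAD, gene id) so ties resolve deterministically
    order = sorted(survivors, key=lambda g: (-mad[g], g))
    kept_set = set(order[:n_keep])
    kept = [g for g in tpm_surv.index if g in kept_set]
    logger.info("MAD filter: %d -> %d genes", len(survivors), len(kept))
    return tpm.loc[kept]


def log_transform(tpm: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); input must be nonnegative."""
    values = tpm.to_numpy()
    if (values < 0).any():
        raise ValueError("negative values in TPM matrix")
    return pd.DataFrame(np.log2(values + 1.0), index=tpm.index, columns=tpm.columns)


def estimate_and_remove_surrogates(expr: pd.DataFrame, metadata: pd.DataFrame,
                                   known_covariates: list[str] | None = None,
                                   n_sv: int = 3) -> SurrogateAdjustment:
    """Estimate surrogate variables by residual PCA and regress them out.

    Each gene is regressed on the trait plus known covariates; the top ``n_sv``
    right singular vectors of the residual matrix are taken as surrogate
    variables (orthonormal across samples). Each gene is then regressed on the
    SVs alone — the trait and covariates are not in this second model, so
    their signal is protected — and the residuals plus gene means form the
    adjusted matrix.
    """
    if known_covariates is None:
        known_covariates = ["sex", "age", "bmi", "ischemic_time"]
    samples = expr.columns
    meta = metadata.loc[samples]
    sv_index = [f"SV{i + 1}" for i in range(n_sv)]
    if n_sv == 0:
        return SurrogateAdjustment(
            n_sv=0,
            sv_matrix=pd.DataFrame(np.empty((0, len(samples))), index=[], columns=samples),
            adjusted=expr.copy(),
        )

    design = _design_matrix(meta, known_covariates)
    D = np.column_stack([np.ones(len(samples)), meta["trait"].to_numpy(dtype=float),
                         design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(D)
    if n_sv >= len(samples) - rank:
        raise ValueError(f"n_sv={n_sv} too large for {len(samples)} samples and design rank {rank}")

    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(D, Y.T, rcond=None)
    residual = Y - (D @ beta).T

    # right singular vectors of the residual matrix = candidate surrogates
    _, _, vt = np.linalg.svd(residual, full_matrices=False)
    sv = vt[:n_sv]  # n_sv x n_samples, orthonormal rows

    D2 = np.column_stack([np.ones(len(samples)), sv.T])
    beta2, *_ = np.linalg.lstsq(D2, Y.T, rcond=None)
    fitted = (D2 @ beta2).T
    adjusted = Y - fitted + Y.mean(axis=1, keepdims=True)

    return SurrogateAdjustment(
        n_sv=n_sv,
        sv_matrix=pd.DataFrame(sv, index=sv_index, columns=samples),
        adjusted=pd.DataFrame(adjusted, index=expr.index, columns=samples),
    )
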