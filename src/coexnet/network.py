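"""Weighted co-expression network construction.

The network is built in the classical weighted co-expression sequence:
absolute Pearson correlation as similarity s_ij, a soft threshold beta chosen
by the scale-free topology criterion, power adjacency a_ij = s_ij^beta, and
the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   l_ij = sum_u a_iu a_uj

with unit diagonal; dissTOM = 1 - TOM is the dissimilarity clustered
downstream. The network is unsigned (|cor|); a signed similarity is available
behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleFreeFit",
    "similarity",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
]


@dataclass
class ScaleFreeFit:
    """Scale-free model fit across a grid of candidate soft thresholds."""

    beta_grid: list[int]
    signed_r2: dict[int, float]
    mean_connectivity: dict[int, float]
    slope: dict[int, float]
    chosen_beta: int
    r2_cut: float
    n_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta_grid,
                "signed_r2": [self.signed_r2[b] for b in self.beta_grid],
                "mean_connectivity": [self.mean_connectivity[b] for b in self.beta_grid],
                "slope": [self.slope[b] for b in self.beta_grid],
            }
        )


def similarity(expr: pd.DataFrame, signed: bool = False) -> pd.DataFrame:
    """Gene-gene co-expression similarity |Pearson r| (genes on rows).

    ``signed=True`` returns (1 + r) / 2 instead of |r|.
    """
    values = expr.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = values.std(axis=1)
    if (sd == 0).any():
        offenders = list(expr.index[sd == 0])
        raise ValueError(f"zero-variance genes: {offenders[:10]}")
    r = np.corrcoef(values)
    s = (1.0 + r) / 2.0 if signed else np.abs(r)
    np.clip(s, 0.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=expr.index, columns=expr.index)


def _connectivity(s: np.ndarray, beta: int) -> np.ndarray:
    a = s**beta
    return a.sum(axis=1) - np.diag(a)


def _scale_free_r2(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R^2 and slope of log-density vs log mean-connectivity.

    Connectivities are split into equal-count (quantile) bins; within each bin
    the degree density is estimated as count / (n * width) and regressed, on
    log10 scales, against the bin's mean connectivity. The R^2 is signed by
    the negative of the slope sign so that only decaying degree distributions
    can score well.
    """
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all values identical")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        raise ValueError("degenerate connectivity: too few distinct values to bin")
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    xs, ys = [], []
    n = len(k)
    for b in range(len(edges) - 1):
        mask = idx == b
        width = edges[b + 1] - edges[b]
        if not mask.any() or width <= 0:
            continue
        mean_k = k[mask].mean()
        density = mask.sum() / (n * width)
        if mean_k > 0 and density > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(density))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity: too few usable bins")
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = float(np.sum((np.asarray(ys) - yhat) ** 2))
    ss_tot = float(np.sum((np.asarray(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(s: pd.DataFrame, beta_grid=range(1, 21), r2_cut: float = 0.85,
                        n_bins: int = 10) -> ScaleFreeFit:
    """Choose the soft threshold by the scale-free topology criterion.

    For each candidate beta the connectivity k_i = sum_j s_ij^beta (diagonal
    excluded) is computed, its distribution fitted on log-log scales, and the
    smallest beta whose signed R^2 reaches ``r2_cut`` is chosen; if none does,
    the best-fitting beta is returned with a warning.
    """
    values = s.to_numpy(dtype=float)
    if len(values) < 20:
        raise ValueError("need at least 20 genes for a meaningful degree fit")
    beta_grid = list(beta_grid)
    signed_r2, mean_k, slopes = {}, {}, {}
    for beta in beta_grid:
        k = _connectivity(values, beta)
        r2, slope = _scale_free_r2(k, n_bins)
        signed_r2[beta] = r2
        slopes[beta] = slope
        mean_k[beta] = float(k.mean())
    chosen = next((b for b in beta_grid if signed_r2[b] >= r2_cut), None)
    if chosen is None:
        chosen = max(beta_grid, key=lambda b: signed_r2[b])
        warnings.warn(
            f"no beta reached signed R^2 >= {r2_cut}; using best beta={chosen} "
            f"(R^2={signed_r2[chosen]:.3f})"
        )
    logger.info("soft threshold beta=%d (signed R^2=%.3f)", chosen, signed_r2[chosen])
    return ScaleFreeFit(beta_grid, signed_r2, mean_k, slopes, chosen, r2_cut, n_bins)


def adjacency(s: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Power adjacency a_ij = s_ij^beta (beta >= 1)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    return s**beta


def topological_overlap(a: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap of a weighted adjacency; diagonal set to 1.

    Uses the matrix-product form l = A @ A with the diagonal of A zeroed, so
    it matches the per-pair sum over shared neighbours exactly.
    """
    values = np.asarray(a, dtype=float)
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = values.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(tom, index=a.index, columns=a.columns)
    return tom


def diss_tom(tom: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap dissimilarity, 1 - TOM (zero diagonal)."""
    return 1.0 - tom
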