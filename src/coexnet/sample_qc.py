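"""Outlier sample detection via a Euclidean-distance sample network.

Within each trait group a sample-sample adjacency is formed by rescaling
pairwise Euclidean distances to [0, 1] (A_uv = 1 - d_uv / max d), each
sample's connectivity k_u is the sum of its adjacencies to the other samples,
and samples whose standardized connectivity Z.k falls below a cutoff
(default -2.5) are flagged. A single pass: the report is computed once, with
no re-standardization after removal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["SampleNetworkReport", "detect_outliers"]


@dataclass
class SampleNetworkReport:
    """Per-group standardized-connectivity report."""

    group_id: str
    connectivity: pd.Series  # k_u
    standardized_connectivity: pd.Series  # Z.k
    flagged_outliers: list[str]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group_id,
                "k": self.connectivity,
                "Z.k": self.standardized_connectivity,
                "flagged": self.connectivity.index.isin(self.flagged_outliers),
            }
        )


def _group_report(expr: pd.DataFrame, group_id: str, cutoff: float) -> SampleNetworkReport:
    samples = list(expr.columns)
    d = squareform(pdist(expr.to_numpy().T))
    dmax = d.max()
    if dmax == 0:
        warnings.warn(f"group {group_id!r}: all samples identical; no outliers flagged")
        zk = pd.Series(0.0, index=samples)
        k = pd.Series(float(len(samples) - 1), index=samples)
        return SampleNetworkReport(group_id, k, zk, [], cutoff)
    adjacency = 1.0 - d / dmax
    np.fill_diagonal(adjacency, 0.0)
    k = adjacency.sum(axis=1)
    sd = k.std(ddof=1)
    zk = np.zeros_like(k) if sd == 0 else (k - k.mean()) / sd
    k_series = pd.Series(k, index=samples)
    zk_series = pd.Series(zk, index=samples)
    flagged = sorted(zk_series.index[zk_series < cutoff])
    return SampleNetworkReport(group_id, k_series, zk_series, flagged, cutoff)


def detect_outliers(expr: pd.DataFrame, metadata: pd.DataFrame,
                    cutoff: float = -2.5) -> dict[str, SampleNetworkReport]:
    """Per trait group, flag samples with standardized connectivity below cutoff.

    Returns a report per group keyed ``"case"`` / ``"control"``.
    """
    trait = metadata.loc[expr.columns, "trait"]
    reports = {}
    for group_id, value in (("control", 0), ("case", 1)):
        cols = expr.columns[trait.to_numpy() == value]
        if len(cols) < 4:
            raise ValueError(f"group {group_id!r} has fewer than 4 samples")
        reports[group_id] = _group_report(expr[cols], group_id, cutoff)
        logger.info("group %s: %d/%d samples flagged", group_id,
                    len(reports[group_id].flagged_outliers), len(cols))
    return reports
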