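"""Condition-specific networks and differential betweenness centrality.

For each module of interest, case and control co-expression networks are
rebuilt from the two sample groups with the shared soft threshold, and each
gene's betweenness centrality is computed on the weighted graph whose edge
lengths are the inverse topological overlap (1 / TOM; TOM = 0 means no edge).
Betweenness of a node v is the sum over unordered pairs {i, j} (both distinct
from v) of the fraction of shortest i-j paths passing through v, accumulated
Brandes-style with a relative tolerance for floating-point length ties. Genes
are then ranked by the absolute change in betweenness between conditions:
large |delta| marks candidate coordinators whose information-transfer role
differs between case and control networks.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network as net

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionNetworks",
    "condition_networks",
    "betweenness",
    "differential_bc",
]


@dataclass
class ConditionNetworks:
    """Case and control TOMs over one module's genes, built with a shared beta."""

    module_id: str
    tom_case: pd.DataFrame
    tom_control: pd.DataFrame
    beta: float


def _group_tom(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    if (sd == 0).any():
        offenders = list(expr.index[sd == 0])
        warnings.warn(f"zero-variance genes within group; correlations set to 0: {offenders[:5]}")
        safe = values.copy()
        safe[sd == 0] += np.arange(values.shape[1]) * 1e-12  # avoid NaN from corrcoef
        r = np.corrcoef(safe)
        r[sd == 0, :] = 0.0
        r[:, sd == 0] = 0.0
        s = np.abs(r)
        np.fill_diagonal(s, 1.0)
        s_df = pd.DataFrame(s, index=expr.index, columns=expr.index)
    else:
        s_df = net.similarity(expr)
    return net.topological_overlap(net.adjacency(s_df, beta))


def condition_networks(expr: pd.DataFrame, metadata: pd.DataFrame, genes: list[str],
                       beta: float, module_id: str = "") -> ConditionNetworks:
    """Case and control TOM networks restricted to one module's genes."""
    trait = metadata.loc[expr.columns, "trait"].to_numpy()
    case_cols = expr.columns[trait == 1]
    control_cols = expr.columns[trait == 0]
    if len(case_cols) < 4 or len(control_cols) < 4:
        raise ValueError("each trait group needs at least 4 samples")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"module genes absent from expression matrix: {missing[:5]}")
    sub = expr.loc[genes]
    return ConditionNetworks(
        module_id=module_id,
        tom_case=_group_tom(sub[case_cols], beta),
        tom_control=_group_tom(sub[control_cols], beta),
        beta=beta,
    )


def betweenness(tom: pd.DataFrame, epsilon_tie: float = 1e-12) -> pd.Series:
    """Weighted betweenness centrality with edge length 1 / TOM.

    Pairs with TOM = 0 have no edge. Brandes accumulation over single-source
    Dijkstra trees; path lengths within a relative ``epsilon_tie`` count as
    tied shortest paths. Each unordered pair contributes once.
    """
    genes = list(tom.index)
    n = len(genes)
    if n == 0:
        raise ValueError("empty module")
    w = np.asarray(tom, dtype=float)
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / w, np.inf)
    np.fill_diagonal(length, np.inf)
    if not np.all(np.isfinite(length) | np.isinf(length)):
        raise ValueError("non-finite edge lengths")
    neighbors = [np.flatnonzero(np.isfinite(length[i])) for i in range(n)]

    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        heap = [(0.0, s)]
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v in neighbors[u]:
                if done[v]:
                    continue
                nd = d + length[u, v]
                tol = epsilon_tie * max(1.0, abs(dist[v]) if np.isfinite(dist[v]) else 0.0)
                if nd < dist[v] - tol:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= tol:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    return pd.Series(bc / 2.0, index=genes, name="BC")  # each unordered pair counted once


def differential_bc(case_bc: pd.Series, control_bc: pd.Series,
                    module_id: str = "") -> pd.DataFrame:
    """Per-gene betweenness change between conditions, ranked by |delta|."""
    if set(case_bc.index) != set(control_bc.index):
        raise ValueError("case and control betweenness must cover the same genes")
    control_bc = control_bc.loc[case_bc.index]
    table = pd.DataFrame(
        {
            "module": module_id,
            "BC_case": case_bc,
            "BC_control": control_bc,
            "delta": case_bc - control_bc,
        }
    )
    table["abs_delta"] = table["delta"].abs()
    # |delta| descending, ties broken by gene id (stable sort over sorted index)
    table = table.sort_index().sort_values("abs_delta", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.drop(columns="abs_delta")
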