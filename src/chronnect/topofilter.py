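"""Topological filtering of windowed connectivity graphs.

The data-driven scheme is the orthogonal-minimal-spanning-trees (OMST)
filter: extract successive edge-disjoint MSTs on distances 1/weight
(favoring strong couplings), and keep the union of the first m* rounds,
where m* maximizes the quality function

    J(m) = GE(union_m) - Cost(union_m),

global efficiency minus wiring cost (retained weight over total weight).
The first MST guarantees a connected backbone; later orthogonal rounds add
the strongest remaining shortcuts until their cost outweighs the
efficiency they buy.

Arbitrary comparison schemes (absolute threshold, edge density, mean
degree) are provided for benchmarking only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree

from .netmetrics import global_efficiency, shortest_distances

logger = logging.getLogger(__name__)

__all__ = [
    "OMSTReport",
    "kruskal_mst",
    "omst_filter",
    "threshold_arbitrary",
    "filter_idfcg",
]


@dataclass
class OMSTReport:
    """Diagnostics for one OMST run: per-round cost, GE and J, and selected m*."""

    rounds: int = 0
    cost: list[float] = field(default_factory=list)
    ge: list[float] = field(default_factory=list)
    j: list[float] = field(default_factory=list)
    m_star: int = 0


def kruskal_mst(weights: np.ndarray) -> np.ndarray:
    """Minimum spanning tree (forest on disconnected input) on lengths 1/w.

    Returns a symmetric boolean mask of tree edges.  Minimizing total
    1/weight keeps the strongest couplings.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not (w > 0).any():
        raise ValueError("empty graph: no positive-weight edges")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    tree = minimum_spanning_tree(csr_matrix(lengths)).toarray()
    mask = (tree > 0) | (tree.T > 0)
    return mask


def omst_filter(
    weights: np.ndarray,
    m_max: int | None = None,
    patience: int = 2,
) -> tuple[np.ndarray, OMSTReport]:
    """Orthogonal-MST filter of a single weighted graph.

    Extracts up to ``m_max`` edge-disjoint MST rounds (default
    floor((N-1)/2)), stopping early after ``patience`` consecutive
    decreases of J; returns the boolean edge mask of the best union and a
    per-round report.  Disconnected inputs are handled per connected
    component (the MST becomes a forest; unreachable pairs contribute zero
    efficiency).
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if m_max is None:
        m_max = max(1, (n - 1) // 2)
    total_weight = w[np.triu_indices(n, 1)].sum()
    if total_weight <= 0:
        raise ValueError("empty graph: no positive-weight edges")

    remaining = w.copy()
    union = np.zeros_like(w, dtype=bool)
    report = OMSTReport()
    masks = []
    decreases = 0
    for m in range(1, m_max + 1):
        if not (remaining > 0).any():
            logger.info("graph exhausted after %d OMST rounds", m - 1)
            break
        tree = kruskal_mst(remaining)
        union = union | tree
        remaining = np.where(tree, 0.0, remaining)
        retained = np.where(union, w, 0.0)
        cost = retained[np.triu_indices(n, 1)].sum() / total_weight
        ge = global_efficiency(shortest_distances(retained))
        report.rounds = m
        report.cost.append(cost)
        report.ge.append(ge)
        report.j.append(ge - cost)
        masks.append(union.copy())
        if m >= 2 and report.j[-1] < report.j[-2]:
            decreases += 1
            if decreases >= patience:
                break
        else:
            decreases = 0

    report.m_star = int(np.argmax(report.j)) + 1
    return masks[report.m_star - 1], report


def threshold_arbitrary(weights: np.ndarray, scheme: str, param: float) -> np.ndarray:
    """Arbitrary filtering schemes: ``absolute``, ``density`` or ``mean_degree``.

    absolute: keep w >= param; density: keep the top ceil(param*N(N-1)/2)
    edges; mean_degree: keep the top ceil(param*N/2) edges.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    vals = w[iu]
    if scheme == "absolute":
        if param < 0:
            raise ValueError("absolute threshold must be >= 0")
        keep = vals >= param
    elif scheme in ("density", "mean_degree"):
        if scheme == "density":
            if not 0 < param <= 1:
                raise ValueError("density must lie in (0, 1]")
            n_keep = int(np.ceil(param * n * (n - 1) / 2))
        else:
            if not 1 <= param <= n - 1:
                raise ValueError("mean degree must lie in [1, N-1]")
            n_keep = int(np.ceil(param * n / 2))
        order = np.argsort(-vals, kind="stable")
        keep = np.zeros(vals.size, dtype=bool)
        keep[order[:n_keep]] = True
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    keep &= vals > 0
    mask = np.zeros_like(w, dtype=bool)
    mask[iu] = keep
    return mask | mask.T


def filter_idfcg(
    idfcg, scheme: str = "omst", param: float | None = None, m_max: int | None = None,
) -> np.ndarray:
    """Apply a per-window topological filter to an IDFCG.

    Statistical filtering has already zeroed non-significant edges
    (mode label 0), so only surviving edges enter the filter.  Returns a
    boolean mask tensor [T x N x N].
    """
    T = idfcg.n_windows
    mask = np.zeros_like(idfcg.strength, dtype=bool)
    for t in range(T):
        w = idfcg.strength[t]
        if not (w > 0).any():
            logger.warning("window %d has no significant edges; empty mask", t)
            continue
        if scheme == "omst":
            mask[t], _ = omst_filter(w, m_max=m_max)
        else:
            if param is None:
                raise ValueError(f"scheme {scheme!r} requires a parameter")
            mask[t] = threshold_arbitrary(w, scheme, param)
    return mask
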