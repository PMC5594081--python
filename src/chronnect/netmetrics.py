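"""Graph metrics on filtered connectivity graphs.

Edge weights are coupling strengths in [0, 1]; a strong coupling means the
two sensors are functionally *close*, so shortest paths run on inverted
weights (length = 1/weight).  Nodal global efficiency of node i is the mean
inverse shortest-path distance to every other node, with unreachable pairs
contributing zero.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "shortest_distances",
    "nodal_global_efficiency",
    "global_efficiency",
    "build_nmts",
    "strength_series",
]


def shortest_distances(weights: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """All-pairs shortest-path distances on edge lengths 1/weight.

    ``mask`` (boolean, same shape) restricts the graph to retained edges.
    Unreachable pairs get ``inf``; the diagonal is zero.
    """
    w = np.asarray(weights, dtype=float)
    if mask is not None:
        w = np.where(mask, w, 0.0)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_matrix(lengths), directed=False)


def nodal_global_efficiency(d: np.ndarray) -> np.ndarray:
    """GE_i = (1/(N-1)) * sum_{j != i} 1/d_ij, with 1/inf := 0."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(d: np.ndarray) -> float:
    """Network-level GE: the mean of the nodal profile."""
    return float(nodal_global_efficiency(d).mean())


def build_nmts(idfcg, mask: np.ndarray | None = None) -> np.ndarray:
    """Nodal global-efficiency time series, shape (n_channels, n_windows).

    Column t is the nodal GE profile of window t's (optionally masked)
    strength graph.
    """
    T, n, _ = idfcg.strength.shape
    out = np.empty((n, T))
    for t in range(T):
        m = mask[t] if mask is not None else None
        out[:, t] = nodal_global_efficiency(shortest_distances(idfcg.strength[t], m))
    return out


def strength_series(idfcg, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-window sum of retained edge weights (each undirected edge once)."""
    w = idfcg.strength
    if mask is not None:
        w = np.where(mask, w, 0.0)
    iu = np.triu_indices(w.shape[1], k=1)
    return w[:, iu[0], iu[1]].sum(axis=1)
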