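"""NNMF + neural-gas symbolization of network-metric time series.

The nodal global-efficiency matrix (windows x sensors) is first
re-parameterized in a low-rank nonnegative space (NNMF), then vector-
quantized with the neural-gas algorithm into k prototypical network
microstates.  k is chosen as the smallest value whose codebook rebuilds
the original matrix with relative Frobenius error below 4%.  A seriation
pass orders the prototypes so that nearby symbols are similar states, and
each window is encoded by its nearest prototype's seriated label, yielding
the microstate symbolic sequence fed to the chronnectomic features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF

logger = logging.getLogger(__name__)

__all__ = [
    "ReducedTrajectory",
    "Codebook",
    "nnmf_reduce",
    "neural_gas",
    "select_k",
    "seriate",
    "encode",
    "fit_microstates",
]


@dataclass
class ReducedTrajectory:
    """NNMF coordinates of the window trajectory.

    ``V`` (T x r) are per-window coordinates, ``basis`` (r x N) the
    nonnegative topography basis so that ``X ≈ V @ basis``.
    """

    V: np.ndarray
    basis: np.ndarray
    rel_error: float


@dataclass
class Codebook:
    """k microstate prototypes in reduced space with seriation order.

    ``prototypes`` is (k, r); ``topographies`` (k, N) are the
    back-projected nodal profiles; ``order`` is the seriated permutation of
    prototype indices, so seriated label ``s`` (1-based) refers to
    prototype ``order[s-1]``.
    """

    prototypes: np.ndarray
    basis: np.ndarray
    occupancy: np.ndarray
    order: np.ndarray
    distortion: float
    rel_error: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.prototypes.shape[0]

    @property
    def topographies(self) -> np.ndarray:
        return self.prototypes @ self.basis

    def partition_matrix(self, V: np.ndarray) -> np.ndarray:
        """One-hot assignment matrix U (T x k) in seriated label order."""
        labels = encode(V, self)
        U = np.zeros((V.shape[0], self.k))
        U[np.arange(V.shape[0]), labels - 1] = 1.0
        return U


def nnmf_reduce(X: np.ndarray, r: int, seed: int = 0, n_restarts: int = 5,
                max_iter: int = 1000, tol: float = 1e-10,
                init: str = "random") -> ReducedTrajectory:
    """Nonnegative factorization X (T x N) ≈ V (T x r) @ basis (r x N).

    Coordinate-descent updates with ``n_restarts`` seeded random restarts,
    keeping the factorization with the smallest Frobenius error.
    ``init='nndsvda'`` uses the deterministic SVD-based start instead
    (restarts then collapse to one), which makes the factorization
    equivariant to sensor permutation.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("NNMF input must be nonnegative")
    if not 1 <= r <= min(X.shape):
        raise ValueError(f"rank {r} outside [1, min(T, N)]")
    best = None
    ss = np.random.SeedSequence(seed)
    if init != "random":
        n_restarts = 1
    for child in ss.spawn(n_restarts):
        rs = int(child.generate_state(1)[0] % (2**31))
        model = NMF(n_components=r, init=init, solver="cd", max_iter=max_iter,
                    tol=tol, random_state=rs)
        with np.errstate(invalid="ignore", divide="ignore"):
            V = model.fit_transform(X)
        err = np.linalg.norm(X - V @ model.components_)
        if best is None or err < best[0]:
            best = (err, V, model.components_)
    err, V, basis = best
    norm = np.linalg.norm(X)
    return ReducedTrajectory(V=V, basis=basis, rel_error=float(err / norm) if norm else 0.0)


def _distortion(V: np.ndarray, prototypes: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = ((V[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    return assign, float(d2[np.arange(len(V)), assign].mean())


def neural_gas(
    V: np.ndarray | ReducedTrajectory,
    k: int,
    n_epochs: int = 100,
    lambda_0: float | None = None,
    lambda_f: float = 0.01,
    eps_0: float = 0.5,
    eps_f: float = 0.005,
    seed: int = 0,
    basis: np.ndarray | None = None,
) -> Codebook:
    """Neural-gas vector quantization of the reduced trajectory.

    Rank-based soft-max updates: on each presentation every prototype moves
    toward the sample by eps(t) * exp(-rank / lambda(t)), with lambda and
    eps decaying exponentially from (k/2, 0.5) to (0.01, 0.005) over
    ``n_epochs`` passes.  Prototypes are initialized at random data points.
    """
    if isinstance(V, ReducedTrajectory):
        basis = V.basis if basis is None else basis
        V = V.V
    V = np.asarray(V, dtype=float)
    T = V.shape[0]
    if k > T:
        raise ValueError("k cannot exceed the number of samples")
    n_distinct = np.unique(V, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({n_distinct})")
    if basis is None:
        basis = np.eye(V.shape[1])
    if lambda_0 is None:
        lambda_0 = max(k / 2.0, 0.5)

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(T, size=k, replace=False)
    proto = V[init_idx].astype(float).copy()

    t_max = n_epochs * T
    step = 0
    for _ in range(n_epochs):
        for idx in rng.permutation(T):
            frac = step / max(t_max - 1, 1)
            lam = lambda_0 * (lambda_f / lambda_0) ** frac
            eps = eps_0 * (eps_f / eps_0) ** frac
            x = V[idx]
            d2 = ((proto - x) ** 2).sum(axis=1)
            ranks = np.argsort(np.argsort(d2))
            proto += (eps * np.exp(-ranks / lam))[:, None] * (x - proto)
            step += 1

    assign, dist = _distortion(V, proto)
    occupancy = np.bincount(assign, minlength=k)
    order = seriate(proto, occupancy)
    return Codebook(prototypes=proto, basis=basis, occupancy=occupancy,
                    order=order, distortion=dist,
                    meta={"seed": seed, "n_epochs": n_epochs})


def reconstruction_error(X: np.ndarray, trajectory: ReducedTrajectory,
                         codebook: Codebook) -> float:
    """Relative Frobenius error of rebuilding X from codevector assignments."""
    assign, _ = _distortion(trajectory.V, codebook.prototypes)
    Xhat = codebook.prototypes[assign] @ codebook.basis
    return float(np.linalg.norm(X - Xhat) / np.linalg.norm(X))


def select_k(
    X: np.ndarray,
    k_range=range(2, 16),
    threshold: float = 0.04,
    r: int = 8,
    seed: int = 0,
    **ng_kwargs,
) -> tuple[int, "Codebook", ReducedTrajectory]:
    """Smallest k whose VQ codebook rebuilds X with relative error < threshold.

    If no k in the range succeeds, the largest is returned with a warning.
    Returns (k, fitted codebook, reduced trajectory).
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    X = np.asarray(X, dtype=float)
    r_eff = min(r, min(X.shape))
    traj = nnmf_reduce(X, r_eff, seed=seed)
    last = None
    for k in k_range:
        cb = neural_gas(traj, k, seed=seed, **ng_kwargs)
        cb.rel_error = reconstruction_error(X, traj, cb)
        last = (k, cb)
        if cb.rel_error < threshold:
            return k, cb, traj
    logger.warning("no k in %s reached reconstruction error < %.3g; using k=%d",
                   k_range, threshold, last[0])
    return last[0], last[1], traj


def seriate(prototypes: np.ndarray, occupancy: np.ndarray) -> np.ndarray:
    """Deterministic prototype ordering: nearest-neighbor chain.

    Starts from the highest-occupancy prototype (ties toward the lower
    index) and repeatedly appends the nearest unvisited prototype, so
    consecutive symbols denote similar states.
    """
    k = prototypes.shape[0]
    start = int(np.argmax(occupancy))
    order = [start]
    remaining = set(range(k)) - {start}
    while remaining:
        cur = prototypes[order[-1]]
        cand = sorted(remaining)
        d2 = [((prototypes[c] - cur) ** 2).sum() for c in cand]
        nxt = cand[int(np.argmin(d2))]
        order.append(nxt)
        remaining.discard(nxt)
    return np.asarray(order)


def encode(V: np.ndarray | ReducedTrajectory, codebook: Codebook) -> np.ndarray:
    """Assign each window the seriated label (1..k) of its nearest prototype."""
    if isinstance(V, ReducedTrajectory):
        V = V.V
    assign, _ = _distortion(np.asarray(V, dtype=float), codebook.prototypes)
    seriated_label = np.empty(codebook.k, dtype=int)
    seriated_label[codebook.order] = np.arange(1, codebook.k + 1)
    return seriated_label[assign]


def fit_microstates(
    X: np.ndarray,
    k: int | None = None,
    k_range=range(2, 16),
    threshold: float = 0.04,
    r: int = 8,
    seed: int = 0,
    **ng_kwargs,
) -> tuple[Codebook, np.ndarray, ReducedTrajectory]:
    """End-to-end NNMF-VQ: reduce, quantize (selecting k if not given), encode.

    ``X`` is the NMTS transposed to windows x sensors.  Returns
    (codebook, symbolic sequence, reduced trajectory).
    """
    X = np.asarray(X, dtype=float)
    if k is None:
        k, cb, traj = select_k(X, k_range=k_range, threshold=threshold, r=r,
                               seed=seed, **ng_kwargs)
    else:
        traj = nnmf_reduce(X, min(r, min(X.shape)), seed=seed)
        cb = neural_gas(traj, k, seed=seed, **ng_kwargs)
        cb.rel_error = reconstruction_error(X, traj, cb)
    return cb, encode(traj, cb), traj
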