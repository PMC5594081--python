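"""Chronnectomic features from symbolic sequences and the IDFCG.

Per subject the feature vector concatenates:

* TR — microstate transition rate (fraction of consecutive windows that
  change state);
* TM — k x k transition probability matrix (normalized by total observed
  transitions, so all entries sum to 1);
* FI — N x N flexibility index: per sensor pair, the rate at which the
  dominant coupling mode changes between consecutive windows (gaining or
  losing significant coupling, label 0, counts as a change);
* comodulogram — 8 x 8 probability distribution of the 36 coupling modes
  over all windows and pairs (within-band on the diagonal, (low, high)
  pairs above it);
* Z(CI) — complexity index (distinct substrings up to a word length)
  z-scored against shuffled sequences;
* ERT — k x k entropy of Markov trajectories (Ekroot & Cover), the
  expected description length in bits of a random path from state i to
  its first visit of state j;
* SampEn — sample entropy of the window-strength time series.

All entropies use log base 2 (bits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "transition_rate",
    "transition_matrix",
    "empirical_markov",
    "flexibility_index",
    "comodulogram",
    "complexity_index",
    "ci_zscore",
    "stationary_distribution",
    "entropy_rate",
    "trajectory_entropy",
    "sample_entropy",
    "ChronnectomicFeatures",
    "compute_chronnectomics",
    "assemble_features",
]


def transition_rate(sts: np.ndarray) -> float:
    """Fraction of consecutive window pairs whose symbol changes."""
    s = np.asarray(sts)
    if s.size < 2:
        raise ValueError("sequence must have length >= 2")
    return float(np.mean(s[1:] != s[:-1]))


def transition_matrix(sts: np.ndarray, k: int) -> np.ndarray:
    """k x k matrix of transition probabilities normalized by total transitions.

    Entry (i, j) is #{t : s_t = i+1, s_{t+1} = j+1} / (len - 1); the whole
    matrix sums to 1 (it is *not* row-stochastic — see
    :func:`empirical_markov` for the Markov-chain kernel).
    """
    s = np.asarray(sts, dtype=int)
    if s.size < 2:
        raise ValueError("sequence must have length >= 2")
    tm = np.zeros((k, k))
    np.add.at(tm, (s[:-1] - 1, s[1:] - 1), 1.0)
    return tm / (s.size - 1)


def empirical_markov(sts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic transition kernel on the states actually visited.

    Returns (P, states) where ``states`` are the sorted distinct symbols
    and ``P[i, j]`` the conditional probability of moving from states[i]
    to states[j].  Rows with no observed outgoing transition (only
    possible for the final symbol) fall back to a self-loop.
    """
    s = np.asarray(sts, dtype=int)
    states = np.unique(s)
    index = {st: i for i, st in enumerate(states)}
    k = states.size
    counts = np.zeros((k, k))
    for a, b in zip(s[:-1], s[1:]):
        counts[index[a], index[b]] += 1
    rows = counts.sum(axis=1)
    P = np.empty_like(counts)
    for i in range(k):
        if rows[i] == 0:
            P[i] = 0.0
            P[i, i] = 1.0
        else:
            P[i] = counts[i] / rows[i]
    return P, states


def flexibility_index(mode_tensor: np.ndarray) -> np.ndarray:
    """Per-pair rate of dominant-mode change between consecutive windows.

    ``mode_tensor`` is [T x N x N]; label 0 (no significant coupling)
    participates in changes — a pair losing or regaining significant
    coupling is reconfiguring.
    """
    m = np.asarray(mode_tensor)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    return np.mean(m[1:] != m[:-1], axis=0)


def comodulogram(mode_tensor: np.ndarray, table=None) -> np.ndarray:
    """8 x 8 probability distribution of the 36 coupling modes.

    Counts every nonzero label over all windows and (upper-triangular)
    sensor pairs; within-band modes land on the diagonal, cross-frequency
    modes at (low band, high band).  Sums to 1 when any nonzero label
    exists; an all-zero tensor yields a zero matrix with a warning.
    """
    if table is None:
        from .coupling import CouplingModeTable

        table = CouplingModeTable()
    m = np.asarray(mode_tensor, dtype=int)
    if m.ndim == 3:
        iu = np.triu_indices(m.shape[1], k=1)
        labels = m[:, iu[0], iu[1]].ravel()
    else:
        labels = m.ravel()
    if (labels < 0).any() or (labels > table.n_modes).any():
        raise ValueError("labels must lie in 0..36")
    counts = np.bincount(labels, minlength=table.n_modes + 1)[1:]
    n_bands = table.n_within
    out = np.zeros((n_bands, n_bands))
    for lab in range(1, table.n_modes + 1):
        i, j = table.band_indices(lab)
        out[i, j] = counts[lab - 1]
    total = out.sum()
    if total == 0:
        logger.warning("no significant couplings; comodulogram is all zero")
        return out
    return out / total


def complexity_index(sts: np.ndarray, max_word_len: int = 7) -> int:
    """Number of distinct contiguous substrings of lengths 1..max_word_len.

    Quantifies the "richness of the language" of the symbolic sequence:
    periodic sequences repeat few words, complex ones many.
    """
    s = [int(x) for x in np.asarray(sts).ravel()]
    if len(s) == 0:
        raise ValueError("empty sequence")
    if len(s) < max_word_len:
        raise ValueError("sequence shorter than max_word_len")
    words = set()
    for length in range(1, max_word_len + 1):
        for start in range(len(s) - length + 1):
            words.add(tuple(s[start : start + length]))
    return len(words)


def ci_zscore(
    sts: np.ndarray, max_word_len: int = 7, n_shuffles: int = 1000, seed: int = 0,
) -> float:
    """Z-score of the complexity index against shuffled surrogates.

    Z = (CI - mean(CI_rand)) / std(CI_rand); returns 0 with a warning when
    the shuffled distribution is degenerate (e.g. a constant sequence).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    s = np.asarray(sts)
    ci = complexity_index(s, max_word_len)
    rng = np.random.default_rng(seed)
    rand = np.array([
        complexity_index(rng.permutation(s), max_word_len) for _ in range(n_shuffles)
    ])
    sd = rand.std()
    if sd == 0:
        logger.warning("degenerate shuffle distribution; Z(CI) set to 0")
        return 0.0
    return float((ci - rand.mean()) / sd)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution mu with mu P = mu, sum(mu) = 1.

    For a reducible chain the computation restricts to the recurrent
    communicating class (warning); transient states get mu = 0.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be row-stochastic")
    n_comp, comp = connected_components(csr_matrix(P > 0), directed=True,
                                        connection="strong")
    support = np.arange(k)
    if n_comp > 1:
        # recurrent class: a strongly connected component with no edge leaving it
        recurrent = None
        for c in range(n_comp):
            members = np.where(comp == c)[0]
            outside = np.where(comp != c)[0]
            if outside.size == 0 or P[np.ix_(members, outside)].sum() == 0:
                recurrent = members
                break
        if recurrent is None:  # pragma: no cover - cannot happen in finite chains
            raise ValueError("no recurrent class found")
        logger.warning("reducible chain; restricting to recurrent class %s", recurrent)
        support = recurrent
    Psub = P[np.ix_(support, support)]
    Psub = Psub / Psub.sum(axis=1, keepdims=True)
    n = Psub.shape[0]
    # solve mu (P - I) = 0 with sum constraint
    A = np.vstack([Psub.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    mu_sub, *_ = np.linalg.lstsq(A, b, rcond=None)
    mu_sub = np.clip(mu_sub, 0, None)
    mu_sub /= mu_sub.sum()
    mu = np.zeros(k)
    mu[support] = mu_sub
    return mu


def entropy_rate(P: np.ndarray, mu: np.ndarray | None = None) -> float:
    """Entropy rate H(X) = -sum_ij mu_i P_ij log2 P_ij in bits."""
    P = np.asarray(P, dtype=float)
    if mu is None:
        mu = stationary_distribution(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    return float(-(mu[:, None] * plogp).sum())


def _row_entropy(P: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    return -plogp.sum(axis=1)


def trajectory_entropy(P: np.ndarray, transposed_a: bool = False) -> np.ndarray:
    """Entropy (bits) of the random trajectory from state i to first arrival at j.

    Ekroot & Cover construction: H = K - K' + H_Delta with
    K = (I - P + A)^{-1} (H* - H_Delta), A the matrix whose every row is
    the stationary distribution, H*_ij = H(P_i) the row entropy, and
    (H_Delta)_ii = H(X)/mu_i.  The diagonal satisfies the recurrence-time
    identity H_ii = H(X)/mu_i exactly.

    ``transposed_a=True`` builds A transposed (A_ij = mu_i), as printed
    in some secondary sources; it does not satisfy the diagonal identity
    and exists for comparison only.
    """
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    n_comp, _ = connected_components(csr_matrix(P > 0), directed=True,
                                     connection="strong")
    if n_comp > 1:
        raise ValueError("trajectory entropy requires an irreducible chain")
    mu = stationary_distribution(P)
    hx = entropy_rate(P, mu)
    A = np.tile(mu, (k, 1))  # rows equal to mu: A_ij = mu_j
    if transposed_a:
        A = A.T
    Hstar = np.tile(_row_entropy(P)[:, None], (1, k))
    Hdelta = np.diag(hx / mu)
    M = np.eye(k) - P + A
    try:
        K = np.linalg.solve(M, Hstar - Hdelta)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError("singular (I - P + A); chain not irreducible") from exc
    Kprime = np.tile(np.diag(K), (k, 1))
    H = K - Kprime + Hdelta
    # numerical dust below zero is clipped; entropies are nonnegative
    return np.where(H < 0, np.where(H > -1e-9, 0.0, H), H)


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) with Chebyshev template matching.

    B counts m-length template pairs closer than ``r`` (default
    0.2 * SD of the series), A the (m+1)-length pairs; self-matches are
    excluded.  Returns +inf with a warning when no matches exist.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= m + 1:
        raise ValueError("series too short for the template length")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    # both template lengths use the same n-m start positions, so a constant
    # series yields A = B and SampEn exactly 0
    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        iu = np.triu_indices(emb.shape[0], k=1)
        return int((d[iu] < r).sum())

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        logger.warning("no template matches (A=%d, B=%d); SampEn undefined", A, B)
        return float("inf")
    return float(-np.log(A / B))


@dataclass
class ChronnectomicFeatures:
    """All per-subject chronnectomic blocks with consistent (k, N)."""

    tr: float
    tm: np.ndarray
    fi: np.ndarray
    comod: np.ndarray
    ci: int
    ci_z: float
    ert: np.ndarray
    sampen: float
    k: int
    n_channels: int


def compute_chronnectomics(
    sts: np.ndarray,
    mode_tensor: np.ndarray,
    strength: np.ndarray,
    k: int,
    table=None,
    max_word_len: int = 7,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ChronnectomicFeatures:
    """Compute every chronnectomic feature block for one subject."""
    sts = np.asarray(sts, dtype=int)
    P, states = empirical_markov(sts)
    ert_full = np.zeros((k, k))
    n_comp, _ = connected_components(csr_matrix(P > 0), directed=True,
                                     connection="strong")
    if n_comp == 1:
        ert = trajectory_entropy(P)
        idx = states - 1
        ert_full[np.ix_(idx, idx)] = ert
    else:
        logger.warning("reducible empirical chain; ERT restricted to recurrent class")
        mu = stationary_distribution(P)
        sup = np.where(mu > 0)[0]
        Psub = P[np.ix_(sup, sup)]
        Psub /= Psub.sum(axis=1, keepdims=True)
        if sup.size >= 1:
            ert = trajectory_entropy(Psub) if sup.size > 1 else np.zeros((1, 1))
            idx = states[sup] - 1
            ert_full[np.ix_(idx, idx)] = ert
    return ChronnectomicFeatures(
        tr=transition_rate(sts),
        tm=transition_matrix(sts, k),
        fi=flexibility_index(mode_tensor),
        comod=comodulogram(mode_tensor, table),
        ci=complexity_index(sts, min(max_word_len, len(sts))),
        ci_z=ci_zscore(sts, min(max_word_len, len(sts)), n_shuffles, seed),
        ert=ert_full,
        sampen=sample_entropy(strength),
        k=k,
        n_channels=mode_tensor.shape[1],
    )


def assemble_features(feats: ChronnectomicFeatures, table=None) -> pd.Series:
    """Flatten the blocks into a named feature vector.

    Layout: TR (1) + TM (k^2) + FI (N^2) + comodulogram (36) + Z(CI) (1)
    + ERT (k^2) + SampEn (1); for k=8, N=64 this is 4,263 entries.  Names
    are stable across runs.
    """
    if table is None:
        from .coupling import CouplingModeTable

        table = CouplingModeTable()
    k, n = feats.k, feats.n_channels
    if feats.tm.shape != (k, k) or feats.ert.shape != (k, k):
        raise ValueError("TM/ERT shape inconsistent with k")
    if feats.fi.shape != (n, n):
        raise ValueError("FI shape inconsistent with channel count")
    names: list[str] = ["TR"]
    values: list[float] = [feats.tr]
    for i in range(k):
        for j in range(k):
            names.append(f"TM_{i + 1}_{j + 1}")
            values.append(feats.tm[i, j])
    for i in range(n):
        for j in range(n):
            names.append(f"FI_{i + 1}_{j + 1}")
            values.append(feats.fi[i, j])
    for lab in range(1, table.n_modes + 1):
        lo, hi = table.mode(lab)
        bi, bj = table.band_indices(lab)
        names.append(f"comod_{lo}_{hi}")
        values.append(feats.comod[bi, bj])
    names.append("CI_z")
    values.append(feats.ci_z)
    for i in range(k):
        for j in range(k):
            names.append(f"ERT_{i + 1}_{j + 1}")
            values.append(feats.ert[i, j])
    names.append("SampEn")
    values.append(feats.sampen)
    if len(set(names)) != len(names):
        raise ValueError("feature names are not unique")
    return pd.Series(values, index=names, dtype=float)
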