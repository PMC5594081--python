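"""Feature selection and age prediction / age-group classification.

Regression path: distance-correlation similarity between features ->
dominant-set clustering (replicator dynamics) -> one representative per
cluster (highest distance correlation with age) -> linear-kernel SVR under
leave-one-out cross-validation.

Classification path: supervised Laplacian score per feature -> permutation
threshold (mean + 2.5 SD of label-shuffled scores) -> extreme learning
machine (random sigmoid hidden layer, ridge least-squares readout) under
LOOCV.

By default feature selection is nested inside each LOOCV fold (no
information from the held-out subject leaks into selection);
``nested=False`` reproduces the cohort-level selection some studies use,
which is optimistic by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import r2_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "ClassificationResult",
    "distance_correlation",
    "dominant_set_clusters",
    "select_representatives",
    "laplacian_score",
    "permutation_threshold",
    "svr_loocv",
    "elm_classify_loocv",
    "regression_pipeline",
    "classification_pipeline",
]


@dataclass
class RegressionResult:
    """LOOCV age-regression outcome."""

    predictions: np.ndarray
    true: np.ndarray
    r2: float
    slope: float
    intercept: float
    selected: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"LOOCV regression over n={len(self.true)} subjects\n"
            f"  R^2 = {self.r2:.3f}\n"
            f"  predicted = {self.slope:.2f} * true + {self.intercept:.2f}"
        )


@dataclass
class ClassificationResult:
    """LOOCV two-group classification outcome (percentages)."""

    predictions: np.ndarray
    true: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    selected: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"LOOCV classification over n={len(self.true)} subjects\n"
            f"  accuracy    = {self.accuracy:.1f}%\n"
            f"  sensitivity = {self.sensitivity:.1f}%\n"
            f"  specificity = {self.specificity:.1f}%"
        )


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation (V-statistic) in [0, 1].

    Double-centers the pairwise Euclidean distance matrices of x and y and
    correlates them; 0 iff (population) independence, 1 for exact linear
    dependence, and sensitive to nonlinear association unlike Pearson's r.
    """
    x = np.asarray(x, dtype=float).reshape(len(np.atleast_1d(x)), -1)
    y = np.asarray(y, dtype=float).reshape(len(np.atleast_1d(y)), -1)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance input; distance correlation set to 0")
        return 0.0

    def centered(z):
        d = cdist(z, z)
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    ax, ay = centered(x), centered(y)
    dcov2 = (ax * ay).mean()
    dvarx = (ax * ax).mean()
    dvary = (ay * ay).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))


def dominant_set_clusters(
    S: np.ndarray,
    min_cluster: int = 2,
    support_tol: float = 1e-5,
    max_iter: int = 5000,
    conv_tol: float = 1e-10,
) -> list[np.ndarray]:
    """Partition features by iterated dominant-set extraction.

    Replicator dynamics x <- x * (S x) / (x' S x) from a uniform start
    converge to a dominant set (a maximally internally-coherent cluster);
    its support is peeled off and the process repeats.  Leftover features
    (or degenerate extractions) become singletons.  Deterministic: the
    initialization is uniform.
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty similarity matrix")
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    n = S.shape[0]
    remaining = list(range(n))
    clusters: list[np.ndarray] = []
    while len(remaining) >= min_cluster:
        sub = S[np.ix_(remaining, remaining)]
        if sub.max() <= 0:
            break
        m = len(remaining)
        # near-uniform start; the tiny index-based tilt deterministically
        # breaks the symmetry of exactly-tied clusters
        x = 1.0 + 1e-4 * np.arange(m) / m
        x /= x.sum()
        for _ in range(max_iter):
            sx = sub @ x
            denom = x @ sx
            if denom <= 0:
                break
            x_new = x * sx / denom
            if np.abs(x_new - x).sum() < conv_tol:
                x = x_new
                break
            x = x_new
        support = np.where(x > support_tol * x.max())[0]
        if support.size < min_cluster or support.size == 0:
            break
        clusters.append(np.array([remaining[i] for i in support]))
        remaining = [r for i, r in enumerate(remaining) if i not in set(support)]
    clusters.extend(np.array([r]) for r in remaining)
    return clusters


def select_representatives(
    partition: list[np.ndarray], features: np.ndarray, age: np.ndarray,
) -> np.ndarray:
    """One feature per cluster: the member with maximal |distcor| with age.

    Ties break toward the lower feature index.  Returns a boolean mask
    over features with exactly one True per cluster.
    """
    F = np.asarray(features, dtype=float)
    covered = np.concatenate(partition) if partition else np.array([], dtype=int)
    if sorted(covered.tolist()) != list(range(F.shape[1])):
        raise ValueError("partition must cover all features exactly once")
    mask = np.zeros(F.shape[1], dtype=bool)
    for cluster in partition:
        scores = [distance_correlation(F[:, f], age) for f in cluster]
        mask[cluster[int(np.argmax(scores))]] = True
    return mask


def laplacian_score(F: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Supervised Laplacian score per feature, oriented so larger = more discriminative.

    The neighborhood graph connects subjects of the same class (weight 1).
    The classical score L_r = f~' L f~ / f~' D f~ is small for features
    that are smooth within classes; we return 1 - L_r in [0, 1] so a high
    weight marks a feature constant within but different between classes.
    Constant features score 0.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("exactly two groups required")
    W = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    dsum = d.sum()
    Ft = F - (d @ F)[None, :] / dsum
    denom = np.einsum("ij,i,ij->j", Ft, d, Ft)
    num = denom - np.einsum("ij,ij->j", Ft, W @ Ft)  # f' L f with L = D - W
    scores = np.zeros(F.shape[1])
    ok = denom > 1e-30
    scores[ok] = 1.0 - num[ok] / denom[ok]
    return scores


def permutation_threshold(
    F: np.ndarray, labels: np.ndarray, n_perm: int = 200, n_std: float = 2.5,
    seed: int = 0,
) -> np.ndarray:
    """Keep features whose Laplacian-score weight beats label-shuffled chance.

    The null is built by recomputing scores under ``n_perm`` label
    permutations; a feature survives when its true weight exceeds
    mean + ``n_std`` * SD of its own permuted weights.
    """
    if n_perm < 50:
        raise ValueError("need at least 50 permutations")
    F = np.asarray(F, dtype=float)
    y = np.asarray(labels)
    true = laplacian_score(F, y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, F.shape[1]))
    for p in range(n_perm):
        null[p] = laplacian_score(F, rng.permutation(y))
    thresh = null.mean(axis=0) + n_std * null.std(axis=0)
    return true > thresh


def _loocv_folds(n: int):
    idx = np.arange(n)
    for i in range(n):
        yield idx[idx != i], np.array([i])


def svr_loocv(
    F: np.ndarray,
    age: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.1,
    select_fn=None,
) -> RegressionResult:
    """Leave-one-out SVR (linear kernel) prediction of age.

    Per fold: (optionally) select features on the training subjects via
    ``select_fn(F_train, age_train) -> mask``, standardize on the training
    subjects, fit, predict the held-out subject.  Reports the coefficient
    of determination and the least-squares line of predicted vs. true age.
    """
    F = np.asarray(F, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(age)
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(age) == 0:
        raise ValueError("degenerate constant target")
    preds = np.empty(n)
    selected_per_fold = []
    for train, test in _loocv_folds(n):
        Ftr, Fte = F[train], F[test]
        if select_fn is not None:
            mask = select_fn(Ftr, age[train])
            if mask.sum() == 0:
                mask = np.ones(F.shape[1], dtype=bool)
            Ftr, Fte = Ftr[:, mask], Fte[:, mask]
            selected_per_fold.append(np.where(mask)[0])
        scaler = StandardScaler().fit(Ftr)
        model = SVR(kernel="linear", C=C, epsilon=epsilon)
        model.fit(scaler.transform(Ftr), age[train])
        preds[test] = model.predict(scaler.transform(Fte))
    slope, intercept = np.polyfit(age, preds, 1)
    return RegressionResult(
        predictions=preds, true=age, r2=float(r2_score(age, preds)),
        slope=float(slope), intercept=float(intercept), selected=selected_per_fold,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def elm_classify_loocv(
    F: np.ndarray,
    labels: np.ndarray,
    n_hidden: int = 100,
    ridge: float = 1e-6,
    seed: int = 0,
    select_fn=None,
) -> ClassificationResult:
    """Leave-one-out extreme-learning-machine classification of two groups.

    The hidden layer is a fixed random sigmoid expansion (input weights
    and biases uniform on [-1, 1], drawn once from ``seed``); only the
    readout is trained, by ridge-regularized least squares on +/-1 targets.
    Sensitivity is the recall of the positive (second) class, specificity
    that of the first.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if min((y == c).sum() for c in classes) < 5:
        raise ValueError("need at least 5 subjects per class")
    t = np.where(y == classes[1], 1.0, -1.0)
    n = len(y)
    rng = np.random.default_rng(seed)
    preds = np.empty(n)
    selected_per_fold = []
    for train, test in _loocv_folds(n):
        Ftr, Fte = F[train], F[test]
        if select_fn is not None:
            mask = select_fn(Ftr, y[train])
            if mask.sum() == 0:
                mask = np.ones(F.shape[1], dtype=bool)
            Ftr, Fte = Ftr[:, mask], Fte[:, mask]
            selected_per_fold.append(np.where(mask)[0])
        scaler = StandardScaler().fit(Ftr)
        Xtr = scaler.transform(Ftr)
        Xte = scaler.transform(Fte)
        d = Xtr.shape[1]
        fold_rng = np.random.default_rng(np.random.SeedSequence([seed, int(test[0])]))
        Win = fold_rng.uniform(-1, 1, size=(d, n_hidden))
        bias = fold_rng.uniform(-1, 1, size=n_hidden)
        Htr = _sigmoid(Xtr @ Win + bias)
        beta = np.linalg.solve(Htr.T @ Htr + ridge * np.eye(n_hidden), Htr.T @ t[train])
        preds[test] = _sigmoid(Xte @ Win + bias) @ beta
    hard = np.where(preds >= 0, classes[1], classes[0])
    pos, neg = classes[1], classes[0]
    acc = 100.0 * np.mean(hard == y)
    sens = 100.0 * np.mean(hard[y == pos] == pos)
    spec = 100.0 * np.mean(hard[y == neg] == neg)
    return ClassificationResult(
        predictions=hard, true=y, accuracy=float(acc), sensitivity=float(sens),
        specificity=float(spec), selected=selected_per_fold,
    )


def distance_correlation_matrix(F: np.ndarray) -> np.ndarray:
    """Pairwise distance correlation between the columns of F (zero diagonal).

    Caches each column's double-centered distance matrix, so the cost is
    one O(n^2) centering per feature plus one inner product per pair.
    """
    F = np.asarray(F, dtype=float)
    n, p = F.shape
    centered = np.empty((p, n, n))
    for f in range(p):
        d = np.abs(F[:, f, None] - F[None, :, f])
        centered[f] = d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()
    flat = centered.reshape(p, -1)
    gram = (flat @ flat.T) / (n * n)  # pairwise dCov^2
    dvar = np.sqrt(np.clip(np.diag(gram), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.sqrt(np.clip(gram, 0, None) / np.outer(dvar, dvar))
    S[~np.isfinite(S)] = 0.0
    np.fill_diagonal(S, 0.0)
    return S


def _regression_select(F: np.ndarray, age: np.ndarray) -> np.ndarray:
    partition = dominant_set_clusters(distance_correlation_matrix(F))
    return select_representatives(partition, F, age)


def regression_pipeline(
    features: pd.DataFrame | np.ndarray, age: np.ndarray, nested: bool = True,
    C: float = 1.0, epsilon: float = 0.1,
) -> RegressionResult:
    """Dominant-set feature selection + linear SVR under LOOCV.

    ``nested=True`` (default) reruns selection inside every fold;
    ``nested=False`` selects once on the whole cohort before LOOCV
    (optimistic, provided for comparability with cohort-level reports).
    """
    F = np.asarray(features, dtype=float)
    age = np.asarray(age, dtype=float)
    if nested:
        return svr_loocv(F, age, C=C, epsilon=epsilon, select_fn=_regression_select)
    mask = _regression_select(F, age)
    res = svr_loocv(F[:, mask], age, C=C, epsilon=epsilon)
    res.selected = [np.where(mask)[0]]
    return res


def classification_pipeline(
    features: pd.DataFrame | np.ndarray, labels: np.ndarray, nested: bool = True,
    n_perm: int = 200, n_hidden: int = 100, seed: int = 0,
) -> ClassificationResult:
    """Laplacian-score + permutation-threshold selection, then ELM under LOOCV."""
    F = np.asarray(features, dtype=float)
    y = np.asarray(labels)

    def select(Ftr, ytr):
        return permutation_threshold(Ftr, ytr, n_perm=n_perm, seed=seed)

    if nested:
        return elm_classify_loocv(F, y, n_hidden=n_hidden, seed=seed, select_fn=select)
    mask = select(F, y)
    if mask.sum() == 0:
        mask = np.ones(F.shape[1], dtype=bool)
    res = elm_classify_loocv(F[:, mask], y, n_hidden=n_hidden, seed=seed)
    res.selected = [np.where(mask)[0]]
    return res
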