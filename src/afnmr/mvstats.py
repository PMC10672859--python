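"""Multivariate modelling and validation.

Pareto scaling, PCA, a NIPALS PLS1 discriminant model (PLS-DA) with VIP
scores, stratified cross-validated Q2 and accuracy, and label-permutation
testing of class separation.

Model notation (per component a):

    w_a  x-weights (unit norm, proportional to X'y)
    t_a  x-scores, t_a = X w_a
    p_a  x-loadings, p_a = X't_a / t_a't_a
    q_a  y-loading, q_a = y't_a / t_a't_a

with X and y deflated after each component.  The class label is coded
{0, 1} and mean-centered before fitting (PLS1).

    VIP_j = sqrt( p_feat * sum_a[ SSY_a (w_aj/||w_a||)^2 ] / sum_a SSY_a ),
    SSY_a = q_a^2 t_a't_a

so that the mean squared VIP over features is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScaledMatrix",
    "PCAModel",
    "PLSDAModel",
    "PermutationResult",
    "pareto_scale",
    "back_transform",
    "pca_fit",
    "plsda_fit",
    "plsda_predict",
    "vip_scores",
    "cross_validate",
    "permutation_test",
]


@dataclass
class ScaledMatrix:
    values: np.ndarray  # samples x features
    column_means: np.ndarray
    column_sds: np.ndarray
    scaling: str  # pareto | unit | none
    zero_variance: np.ndarray = field(default_factory=lambda: np.array([], bool))


@dataclass
class PCAModel:
    scores: np.ndarray  # samples x ncomp
    loadings: np.ndarray  # features x ncomp (orthonormal columns)
    explained_variance_fraction: np.ndarray


@dataclass
class PLSDAModel:
    ncomp: int
    weights: np.ndarray  # features x ncomp (w_a, unit norm)
    x_loadings: np.ndarray  # features x ncomp (p_a)
    y_loadings: np.ndarray  # ncomp (q_a)
    scores: np.ndarray  # samples x ncomp (t_a)
    vip: np.ndarray
    r2x_cum: float
    r2y_cum: float
    y_mean: float
    q2_cum: float = np.nan
    cv_accuracy: float = np.nan


@dataclass
class PermutationResult:
    n_permutations: int
    observed_statistic: float
    permuted_statistics: np.ndarray
    p_value: float


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def pareto_scale(matrix: np.ndarray, scaling: str = "pareto") -> ScaledMatrix:
    """Column-wise (x - mean) / sqrt(sd) scaling (sd with ddof=1).

    Zero-variance columns are centered only and flagged.  ``scaling``
    may also be "unit" (autoscaling) or "none" (centering only).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = sds == 0.0
    if scaling == "pareto":
        denom = np.sqrt(sds)
    elif scaling == "unit":
        denom = sds.copy()
    elif scaling == "none":
        denom = np.ones_like(sds)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    denom = np.where(zero, 1.0, denom)
    return ScaledMatrix((X - means) / denom, means, sds, scaling, zero)


def back_transform(scaled: ScaledMatrix) -> np.ndarray:
    """Exact inverse of :func:`pareto_scale`."""
    if scaled.scaling == "pareto":
        denom = np.sqrt(scaled.column_sds)
    elif scaled.scaling == "unit":
        denom = scaled.column_sds.copy()
    else:
        denom = np.ones_like(scaled.column_sds)
    denom = np.where(scaled.zero_variance, 1.0, denom)
    return scaled.values * denom + scaled.column_means


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(scaled: ScaledMatrix, ncomp: int = 2) -> PCAModel:
    """Principal components of the scaled (already centered) matrix via
    SVD; scores = data x loadings."""
    X = scaled.values
    n, p = X.shape
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(samples-1, features)")
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = vt[:ncomp].T
    return PCAModel(
        scores=Xc @ loadings,
        loadings=loadings,
        explained_variance_fraction=(s[:ncomp] ** 2) / total,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS PLS1)
# ---------------------------------------------------------------------------

def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    for c in classes:
        if int(np.sum(labels == c)) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return (labels == classes[-1]).astype(float)


def plsda_fit(scaled: ScaledMatrix, labels, ncomp: int = 3) -> PLSDAModel:
    """NIPALS PLS1 discriminant model on a {0,1}-coded centered label."""
    X0 = scaled.values.copy()
    y01 = _encode_labels(labels)
    y_mean = float(y01.mean())
    y = y01 - y_mean
    n, p = X0.shape
    ncomp = min(ncomp, min(n - 1, p))

    ssx0 = float(np.sum(X0**2))
    ssy0 = float(np.sum(y**2))
    X, yr = X0.copy(), y.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    Q = np.zeros(ncomp)
    T = np.zeros((n, ncomp))
    for a in range(ncomp):
        w = X.T @ yr
        nw = np.linalg.norm(w)
        if nw == 0:
            ncomp = a
            W, P, Q, T = W[:, :a], P[:, :a], Q[:a], T[:, :a]
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            ncomp = a
            W, P, Q, T = W[:, :a], P[:, :a], Q[:a], T[:, :a]
            break
        pvec = (X.T @ t) / tt
        q = float(yr @ t) / tt
        X = X - np.outer(t, pvec)
        yr = yr - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t

    r2x = 1.0 - float(np.sum(X**2)) / ssx0 if ssx0 > 0 else 0.0
    r2y = 1.0 - float(np.sum(yr**2)) / ssy0 if ssy0 > 0 else 0.0
    model = PLSDAModel(
        ncomp=ncomp, weights=W, x_loadings=P, y_loadings=Q, scores=T,
        vip=np.array([]), r2x_cum=r2x, r2y_cum=r2y, y_mean=y_mean,
    )
    model.vip = vip_scores(model)
    return model


def plsda_predict(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted (uncentered) class response for new rows of the scaled
    data space: y_hat = X b + y_mean with b = W (P'W)^-1 q."""
    if model.ncomp == 0:
        return np.full(np.atleast_2d(X_new).shape[0], model.y_mean)
    b = model.weights @ np.linalg.solve(
        model.x_loadings.T @ model.weights, model.y_loadings
    )
    return np.atleast_2d(X_new) @ b + model.y_mean


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; mean squared VIP = 1."""
    W, T, Q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    if model.ncomp == 0:
        return np.zeros(p)
    ssy = Q**2 * np.einsum("ia,ia->a", T, T)
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    num = (W**2 / wnorm2) @ ssy
    denom = float(np.sum(ssy))
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * num / denom)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    scaled: ScaledMatrix, labels, ncomp: int = 3, folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold Q2 and classification accuracy.

    Q2 = 1 - PRESS/TSS on held-out labels (TSS against the training-fold
    mean); accuracy thresholds the predicted response at 0.5.
    """
    y01 = _encode_labels(labels)
    smallest = int(min(np.sum(y01 == 0), np.sum(y01 == 1)))
    if folds > smallest:
        raise ValueError(
            f"folds={folds} exceeds the smaller class size {smallest}; "
            f"use folds <= {smallest}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = tss = 0.0
    correct = 0
    X = scaled.values
    for tr, te in skf.split(X, y01):
        sub = ScaledMatrix(
            X[tr] - X[tr].mean(axis=0), X[tr].mean(axis=0),
            scaled.column_sds, "none",
        )
        m = plsda_fit(sub, y01[tr], ncomp=ncomp)
        yhat = plsda_predict(m, X[te] - sub.column_means)
        press += float(np.sum((y01[te] - yhat) ** 2))
        tss += float(np.sum((y01[te] - y01[tr].mean()) ** 2))
        correct += int(np.sum((yhat >= 0.5) == (y01[te] == 1.0)))
    q2 = 1.0 - press / tss if tss > 0 else 0.0
    return q2, correct / y01.size


# ---------------------------------------------------------------------------
# Permutation testing
# ---------------------------------------------------------------------------

def _separation_statistic(scores: np.ndarray, y01: np.ndarray) -> float:
    """Between/within class sum-of-squares ratio of the PLS scores."""
    if scores.size == 0:
        return 0.0
    g0, g1 = scores[y01 == 0.0], scores[y01 == 1.0]
    mu, mu0, mu1 = scores.mean(axis=0), g0.mean(axis=0), g1.mean(axis=0)
    between = g0.shape[0] * np.sum((mu0 - mu) ** 2) + g1.shape[0] * np.sum((mu1 - mu) ** 2)
    within = float(np.sum((g0 - mu0) ** 2) + np.sum((g1 - mu1) ** 2))
    return float(between / within) if within > 0 else np.inf


def permutation_test(
    scaled: ScaledMatrix, labels, ncomp: int = 3, n_perm: int = 1000,
    statistic: str = "class-separation", seed: int = 0, folds: int = 5,
) -> PermutationResult:
    """Label-permutation test of the PLS-DA model.

    ``statistic`` is either "class-separation" (between/within sum of
    squares of the model scores) or "cv-accuracy".  The p-value is
    (1 + #{permuted >= observed}) / (1 + n_perm), so the smallest
    attainable value with 1000 permutations is 1/1001.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y01 = _encode_labels(labels)
    rng = np.random.default_rng(seed)

    def stat(y):
        if statistic == "class-separation":
            m = plsda_fit(scaled, y, ncomp=ncomp)
            return _separation_statistic(m.scores, np.asarray(y, float))
        if statistic == "cv-accuracy":
            k = min(folds, int(min(np.sum(y == 0), np.sum(y == 1))))
            _, acc = cross_validate(scaled, y, ncomp=ncomp, folds=k,
                                    seed=int(rng.integers(2**31)))
            return acc
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = stat(y01)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        permuted[b] = stat(rng.permutation(y01))
    p = (1.0 + float(np.sum(permuted >= observed))) / (1.0 + n_perm)
    return PermutationResult(n_perm, observed, permuted, p)
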