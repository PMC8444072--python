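"""Feature pipeline: Z-score, t-statistic selection, Q-mode PCA, Fisher LDA.

Designed for the p >> n regime of moment features: PCA is computed
through the thin SVD of the centered n x p matrix (Q-mode), so scores
are at most n x n, and Fisher LDA operates in the retained component
space, yielding s - 1 discriminant coordinates for s classes.  Test
samples are mapped by centering with the training means, projecting on
the retained loadings, and multiplying by the discriminant weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "Scaler",
    "PCAModel",
    "FeatureSpaceModel",
    "zscore_fit",
    "zscore_apply",
    "zscore_fit_apply",
    "t_statistics",
    "t_select",
    "qmode_pca_fit",
    "pca_project",
    "lda_fit",
    "lda_project",
    "fit_feature_space",
    "transform_feature_space",
]


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    sd: np.ndarray  # sample (n-1) standard deviation; 0 marks constant features


def zscore_fit(X: np.ndarray) -> Scaler:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("Z-scoring requires a 2-D matrix with n >= 2 rows")
    return Scaler(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1))


def zscore_apply(X: np.ndarray, scaler: Scaler) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = np.where(scaler.sd > 0, scaler.sd, 1.0)
    Z = (X - scaler.mean) / sd
    # constant features carry no information; keep them as exact zeros
    Z[:, scaler.sd == 0] = 0.0
    return Z


def zscore_fit_apply(X: np.ndarray) -> tuple[np.ndarray, Scaler]:
    scaler = zscore_fit(X)
    return zscore_apply(X, scaler), scaler


def t_statistics(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per feature (2 classes).

    Features with zero variance in both classes receive t = 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("t-statistic selection requires exactly two classes")
    Xa, Xb = X[labels == classes[0]], X[labels == classes[1]]
    na, nb = len(Xa), len(Xb)
    if na < 2 or nb < 2:
        raise ValueError("each class needs at least two samples")
    va = Xa.var(axis=0, ddof=1)
    vb = Xb.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def t_select(X: np.ndarray, labels: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices of the top ``ceil(fraction * p)`` features by |t|, ascending.

    Ties in |t| are broken toward the smaller feature index so the
    selection is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    t = t_statistics(X, labels)
    p = t.size
    k = int(np.ceil(fraction * p))
    order = np.lexsort((np.arange(p), -np.abs(t)))
    return np.sort(order[:k])


@dataclass(frozen=True)
class PCAModel:
    """Q-mode PCA fit: training mean, loadings, variance ratios, cut k."""

    mean: np.ndarray  # (p,)
    components: np.ndarray  # (r, p) rows = loadings of all r components
    explained_variance_ratio: np.ndarray  # (r,)
    scores: np.ndarray  # (n, r) training scores V
    k: int  # retained components
    beta: float | None  # variance threshold used, if any


def qmode_pca_fit(
    X: np.ndarray, beta: float | None = 0.95, n_components: int | None = None
) -> PCAModel:
    """PCA of a (possibly p >> n) matrix via thin SVD of the centered data.

    Truncation is either by variance threshold ``beta`` (smallest k
    whose cumulative explained-variance ratio reaches beta) or by a
    fixed component count ``n_components``.  Component signs are fixed
    by making the largest-magnitude loading of each component positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with n >= 2 rows")
    if n_components is None:
        if beta is None or not 0.0 < beta <= 1.0:
            raise ValueError("beta must lie in (0, 1] when n_components is not given")
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    if n_components is not None:
        k = int(min(n_components, len(s)))
    else:
        k = int(np.searchsorted(np.cumsum(ratio), beta - 1e-12) + 1)
        k = min(k, len(s))
    return PCAModel(
        mean=mean,
        components=Vt,
        explained_variance_ratio=ratio,
        scores=U * s,
        k=k,
        beta=beta if n_components is None else None,
    )


def pca_project(X_new: np.ndarray, model: PCAModel) -> np.ndarray:
    """Map rows into the retained principal-component space (n_new x k)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.mean.size:
        raise ValueError(
            f"expected {model.mean.size} feature columns, got {X_new.shape[1]}"
        )
    return (X_new - model.mean) @ model.components[: model.k].T


@dataclass(frozen=True)
class LDAModel:
    weights: np.ndarray  # (k, s-1)
    classes: np.ndarray


def lda_fit(V: np.ndarray, labels: np.ndarray, ridge: float | None = None) -> LDAModel:
    """Fisher discriminant directions in the component space.

    Solves the generalized eigenproblem ``Sb a = lambda Sw a`` and
    keeps the s - 1 leading directions.  The within-class scatter is
    ridge-regularized (``eps * trace(Sw) / k``) when singular, which is
    the typical case after aggressive PCA truncation with few samples
    per class.  Column signs are fixed by making the largest-magnitude
    entry of each direction positive.
    """
    V = np.asarray(V, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    s = classes.size
    if s < 2:
        raise ValueError("LDA requires at least two classes")
    n, k = V.shape
    if k < s - 1:
        raise ValueError(f"need at least s-1={s - 1} dimensions, got {k}")
    grand = V.mean(axis=0)
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for c in classes:
        Vc = V[labels == c]
        if len(Vc) < 2:
            raise ValueError(f"class {c!r} has fewer than two samples")
        mu = Vc.mean(axis=0)
        D = Vc - mu
        Sw += D.T @ D
        d = (mu - grand)[:, None]
        Sb += len(Vc) * (d @ d.T)
    eps = ridge if ridge is not None else 1e-8 * np.trace(Sw) / k
    if eps <= 0:
        eps = 1e-8
    # regularize whenever Sw is (near-)singular
    if np.linalg.matrix_rank(Sw) < k:
        Sw = Sw + eps * np.eye(k)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][: s - 1]
    A = evecs[:, order]
    flip = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    flip[flip == 0] = 1.0
    return LDAModel(weights=A * flip[None, :], classes=classes)


def lda_project(scores: np.ndarray, lda: LDAModel | np.ndarray) -> np.ndarray:
    """Map component scores into discriminant coordinates (n x (s-1))."""
    A = lda.weights if isinstance(lda, LDAModel) else np.asarray(lda, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != A.shape[0]:
        raise ValueError(f"expected {A.shape[0]} score columns, got {scores.shape[1]}")
    return scores @ A


@dataclass(frozen=True)
class FeatureSpaceModel:
    """Fitted scaler + feature selection + PCA + LDA, end to end."""

    scaler: Scaler
    selected: np.ndarray | None
    pca: PCAModel
    lda: LDAModel

    @property
    def classes(self) -> np.ndarray:
        return self.lda.classes


def fit_feature_space(
    X: np.ndarray,
    labels: np.ndarray,
    select_fraction: float | None = None,
    beta: float | None = 0.95,
    n_components: int | None = None,
) -> FeatureSpaceModel:
    """Fit the full raw-features -> discriminant-coordinates pipeline.

    ``select_fraction`` enables top-|t| feature selection (two-class
    problems only); ``beta`` / ``n_components`` control the PCA cut.
    """
    X = np.asarray(X, dtype=float)
    Z, scaler = zscore_fit_apply(X)
    selected = None
    if select_fraction is not None:
        selected = t_select(Z, labels, select_fraction)
        Z = Z[:, selected]
    pca = qmode_pca_fit(Z, beta=beta, n_components=n_components)
    k = max(pca.k, np.unique(labels).size - 1)  # LDA needs >= s-1 dims
    if k != pca.k:
        pca = PCAModel(
            mean=pca.mean,
            components=pca.components,
            explained_variance_ratio=pca.explained_variance_ratio,
            scores=pca.scores,
            k=min(k, pca.components.shape[0]),
            beta=pca.beta,
        )
    V = pca.scores[:, : pca.k]
    lda = lda_fit(V, labels)
    return FeatureSpaceModel(scaler=scaler, selected=selected, pca=pca, lda=lda)


def transform_feature_space(X: np.ndarray, model: FeatureSpaceModel) -> np.ndarray:
    """Map raw feature rows into the fitted discriminant space."""
    Z = zscore_apply(np.atleast_2d(np.asarray(X, dtype=float)), model.scaler)
    if model.selected is not None:
        Z = Z[:, model.selected]
    return lda_project(pca_project(Z, model.pca), model.lda)
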