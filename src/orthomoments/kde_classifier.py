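"""Gaussian kernel density discriminant classifier.

For each class a product-Gaussian kernel density estimate with
per-dimension bandwidths is fitted to the training points; a query is
assigned posterior probabilities proportional to prior times estimated
density and classified by the maximum.  With empirical priors this is
a posterior rule (needed for a calibrated probability of malignancy);
with uniform priors it reduces to pure maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["KernelDiscriminantModel", "kd_fit", "kd_predict", "scott_bandwidth"]


def scott_bandwidth(points: np.ndarray) -> np.ndarray:
    """Scott's rule per dimension: ``h_j = sd_j * n ** (-1 / (d + 4))``."""
    points = np.atleast_2d(points)
    n, d = points.shape
    sd = points.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    return sd * n ** (-1.0 / (d + 4))


@dataclass(frozen=True)
class KernelDiscriminantModel:
    classes: np.ndarray
    points: tuple[np.ndarray, ...]  # per-class training points, (n_c, d)
    bandwidths: np.ndarray  # (s, d), all > 0
    log_priors: np.ndarray  # (s,)
    positive_label: object | None = None

    @property
    def d(self) -> int:
        return self.points[0].shape[1]


def kd_fit(
    Z: np.ndarray,
    labels: np.ndarray,
    bandwidth: str | float = "scott",
    priors: str = "empirical",
    positive_label=None,
) -> KernelDiscriminantModel:
    """Fit per-class Gaussian KDEs in the d-dimensional feature space.

    ``bandwidth`` is ``"scott"`` or a fixed positive number applied to
    every dimension of every class.  Classes whose Scott bandwidth is
    degenerate in some dimension (one point, or zero spread) fall back
    to a global fixed bandwidth for those entries, with a warning.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pts, bws, counts = [], [], []
    global_h = scott_bandwidth(Z)
    fallback = float(np.mean(global_h[global_h > 0])) if np.any(global_h > 0) else 1.0
    for c in classes:
        P = Z[labels == c]
        if len(P) == 0:
            raise ValueError(f"class {c!r} has no training points")
        if isinstance(bandwidth, str):
            if bandwidth != "scott":
                raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
            h = scott_bandwidth(P)
            if np.any(h <= 0):
                warnings.warn(
                    f"class {c!r}: degenerate Scott bandwidth, using global fallback",
                    stacklevel=2,
                )
                h = np.where(h > 0, h, fallback)
        else:
            if bandwidth <= 0:
                raise ValueError("fixed bandwidth must be positive")
            h = np.full(Z.shape[1], float(bandwidth))
        pts.append(P)
        bws.append(h)
        counts.append(len(P))
    counts = np.asarray(counts, dtype=float)
    if priors == "empirical":
        pri = counts / counts.sum()
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    return KernelDiscriminantModel(
        classes=classes,
        points=tuple(pts),
        bandwidths=np.vstack(bws),
        log_priors=np.log(pri),
        positive_label=positive_label,
    )


def _class_log_density(P: np.ndarray, h: np.ndarray, Znew: np.ndarray) -> np.ndarray:
    # log mean of product Gaussians centered at the training points;
    # distant queries may overflow to -inf, handled by the caller
    diff = (Znew[:, None, :] - P[None, :, :]) / h[None, None, :]
    with np.errstate(over="ignore"):
        log_kernel = -0.5 * np.sum(diff**2, axis=2) - np.sum(np.log(h)) - 0.5 * P.shape[1] * np.log(2 * np.pi)
    return logsumexp(log_kernel, axis=1) - np.log(len(P))


def kd_predict(
    model: KernelDiscriminantModel, Z_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class posterior probabilities for query points.

    Posteriors are prior-weighted normalized densities; the predicted
    label is the argmax with ties broken by class order.  Queries where
    every class density underflows to zero are assigned to the nearest
    class centroid (posterior mass 1 on that class) with a warning.
    """
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    if Z_new.shape[1] != model.d:
        raise ValueError(f"expected {model.d} columns, got {Z_new.shape[1]}")
    log_post = np.stack(
        [
            model.log_priors[i] + _class_log_density(model.points[i], model.bandwidths[i], Z_new)
            for i in range(len(model.classes))
        ],
        axis=1,
    )
    bad = ~np.isfinite(log_post).any(axis=1)
    norm = logsumexp(log_post, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        proba = np.exp(log_post - norm)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} query point(s) had vanishing density in every class; "
            "falling back to nearest class centroid",
            stacklevel=2,
        )
        centroids = np.stack([P.mean(axis=0) for P in model.points])
        for i in np.where(bad)[0]:
            dist = np.linalg.norm(centroids - Z_new[i], axis=1)
            proba[i] = 0.0
            proba[i, int(np.argmin(dist))] = 1.0
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, proba


def p_positive(model: KernelDiscriminantModel, proba: np.ndarray) -> np.ndarray:
    """Posterior probability column of the designated positive class."""
    if model.positive_label is None:
        raise ValueError("model has no designated positive label")
    idx = int(np.where(model.classes == model.positive_label)[0][0])
    return proba[:, idx]
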