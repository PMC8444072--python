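"""Weighted Krawtchouk polynomial bases, moments, and invariant features.

The Krawtchouk polynomial of order ``n`` on the ``N``-point grid
``x = 0..N-1`` with success probability ``p`` is the hypergeometric
series ``k_n(x) = 2F1(-n, -x; -(N-1); 1/p)``.  The *weighted* polynomial
``kbar_n(x) = k_n(x) * sqrt(w(x)/rho(n))`` — with ``w`` the binomial
probability mass and ``rho(n)`` the squared norm — makes the family
orthonormal: the ``l x N`` matrix ``K`` of weighted values satisfies
``K @ K.T = I``.

Numerical evaluation does not use the hypergeometric sum.  The weighted
Krawtchouk vectors are the eigenvectors of a symmetric tridiagonal
Jacobi operator with integer eigenvalues ``0..N-1`` (the symmetrized
three-term recurrence in ``x``), so the basis is obtained from
``scipy.linalg.eigh_tridiagonal``.  This is stable for every order up
to ``N`` — the textbook recurrence in ``n`` loses orthogonality
catastrophically once ``n`` exceeds roughly ``N/2`` — and inherits
machine-precision orthonormality from the symmetric eigensolver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .preprocess import crop_pad

__all__ = [
    "KrawtchoukBasis",
    "KrawtchoukMoments",
    "krawtchouk_basis",
    "km_moments",
    "km_reconstruct",
    "km_invariant_features",
    "pose_normalize",
]


@dataclass(frozen=True)
class KrawtchoukBasis:
    """Row-orthonormal matrix of weighted Krawtchouk polynomial values.

    ``K[n, x] = kbar_n(x; p, N-1)`` for orders ``n = 0..l-1`` and grid
    points ``x = 0..N-1``.
    """

    K: np.ndarray
    l: int
    N: int
    p: float


@dataclass(frozen=True)
class KrawtchoukMoments:
    """Krawtchouk moment matrix ``Q`` of an ``N x M`` image at order ``l``."""

    Q: np.ndarray
    source_shape: tuple[int, int]
    l: int
    p: float


def krawtchouk_basis(l: int, N: int, p: float = 0.5) -> KrawtchoukBasis:
    """Weighted Krawtchouk basis of order ``l`` on ``N`` grid points.

    Parameters
    ----------
    l
        Number of polynomials (orders ``0..l-1``); at most ``N``, since
        only ``N`` orthogonal polynomials exist on ``N`` points.
    N
        Grid length.
    p
        Binomial weight parameter in (0, 1).  ``p = 0.5`` centers the
        weight on the middle of the grid.
    """
    if not 1 <= l <= N:
        raise ValueError(f"order l={l} must satisfy 1 <= l <= N={N}")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    x = np.arange(N)
    diag = p * (N - 1 - x) + x * (1 - p)
    off = -np.sqrt(p * (1 - p) * (x[:-1] + 1) * (N - 1 - x[:-1]))
    if N == 1:
        K = np.ones((1, 1))
        return KrawtchoukBasis(K=K, l=1, N=1, p=p)
    _, vec = eigh_tridiagonal(diag, off, select="i", select_range=(0, l - 1))
    K = vec.T
    # The eigensolver returns each row up to an overall sign.  Anchoring
    # at x = 0 (where k_n(0) = 1 > 0) is unreliable: kbar_n(0) carries a
    # sqrt-binomial weight that underflows below eigenvector noise for
    # large N.  Instead anchor every row at its largest-magnitude entry
    # and take the exact sign of the polynomial there from a terminating
    # rational sum (the weight is positive, so sign(kbar) = sign(k)).
    for n in range(l):
        x_star = int(np.argmax(np.abs(K[n])))
        s = _exact_poly_sign(n, x_star, p, N)
        if s != 0 and np.sign(K[n, x_star]) != s:
            K[n] = -K[n]
    return KrawtchoukBasis(K=K, l=l, N=N, p=p)


def _exact_poly_sign(n: int, x: int, p: float, N: int) -> int:
    """Sign of k_n(x; p, N-1) from its terminating series in exact rationals."""
    from fractions import Fraction

    pr = Fraction(p)
    total, term = Fraction(0), Fraction(1)
    for k in range(min(n, x) + 1):
        total += term
        denom = (-(N - 1) + k) * (k + 1)
        if denom == 0:
            break
        term = term * Fraction((-n + k) * (-x + k), denom) / pr
    return (total > 0) - (total < 0)


def km_moments(
    img: np.ndarray, basis_x: KrawtchoukBasis, basis_y: KrawtchoukBasis
) -> KrawtchoukMoments:
    """Krawtchouk moments ``Q = K1 @ A @ K2.T`` of a rectangular image.

    ``basis_x`` spans the row coordinate (length = number of rows) and
    ``basis_y`` the column coordinate.  ``Q[n, m]`` equals the double
    sum of ``kbar_n(x) * kbar_m(y) * f(x, y)`` over all pixels.
    """
    img = np.asarray(img, dtype=float)
    N, M = img.shape
    if basis_x.N != N or basis_y.N != M:
        raise ValueError(
            f"basis lengths ({basis_x.N}, {basis_y.N}) do not match image shape {img.shape}"
        )
    if basis_x.l != basis_y.l:
        raise ValueError("row and column bases must share the same order")
    Q = basis_x.K @ img @ basis_y.K.T
    return KrawtchoukMoments(Q=Q, source_shape=(N, M), l=basis_x.l, p=basis_x.p)


def km_reconstruct(
    moments: KrawtchoukMoments, basis_x: KrawtchoukBasis, basis_y: KrawtchoukBasis
) -> np.ndarray:
    """Inverse transform ``A = K1.T @ Q @ K2``; exact when ``l = N = M``."""
    if (basis_x.N, basis_y.N) != moments.source_shape:
        raise ValueError("basis lengths do not match the moment source shape")
    if basis_x.l != moments.l or basis_y.l != moments.l:
        raise ValueError("basis order does not match the moment order")
    return basis_x.K.T @ moments.Q @ basis_y.K


def _moments_upto3(img: np.ndarray) -> dict[str, float]:
    N, M = img.shape
    x = np.arange(N)[:, None]
    y = np.arange(M)[None, :]
    m00 = img.sum()
    cx = (img * x).sum() / m00
    cy = (img * y).sum() / m00
    dx, dy = x - cx, y - cy
    return {
        "m00": m00,
        "cx": cx,
        "cy": cy,
        "mu20": (img * dx * dx).sum(),
        "mu02": (img * dy * dy).sum(),
        "mu11": (img * dx * dy).sum(),
    }


def pose_normalize(
    img: np.ndarray, mass_fraction: float = 0.25, frame: tuple[int, int] | None = None
) -> np.ndarray:
    """Translation/rotation/scale normalization of an image's intensity mass.

    The center of mass is moved to the frame center, the principal axis
    of the intensity distribution is rotated onto the column (width)
    direction, and the image is scaled isotropically so its total mass
    equals ``mass_fraction`` of the frame area.  The residual 180-degree
    ambiguity of the principal axis is resolved by requiring the
    third-order central moment along the principal axis to be
    non-negative.
    """
    from skimage.transform import AffineTransform, warp

    img = np.asarray(img, dtype=float)
    if frame is None:
        frame = img.shape
    H, W = frame
    m = _moments_upto3(img)
    if m["m00"] <= 0:
        raise ValueError("cannot pose-normalize an image with zero total mass")
    # principal axis of the (row, col) covariance; angle measured from
    # the column axis so theta = 0 means the shape is already horizontal
    theta = 0.5 * np.arctan2(2.0 * m["mu11"], m["mu02"] - m["mu20"])
    scale = np.sqrt(mass_fraction * H * W / m["m00"])

    def _transform(flip: bool) -> np.ndarray:
        # rotate by -theta to bring the principal axis onto the column
        # direction; flip adds a half turn to fix the axis sign
        ang = -theta + (np.pi if flip else 0.0)
        cos, sin = np.cos(ang), np.sin(ang)
        rot = np.array([[cos, -sin], [sin, cos]])  # acts on (col, row)
        fwd = AffineTransform(translation=(-m["cy"], -m["cx"]))
        fwd = fwd + AffineTransform(matrix=np.block([[rot, np.zeros((2, 1))], [np.zeros((1, 2)), 1]]))
        fwd = fwd + AffineTransform(scale=scale)
        fwd = fwd + AffineTransform(translation=((W - 1) / 2.0, (H - 1) / 2.0))
        out = warp(img, fwd.inverse, output_shape=(H, W), order=1, cval=0.0)
        return np.clip(out, 0.0, 1.0)

    out = _transform(flip=False)
    y = np.arange(W)[None, :]
    cy = (out * y).sum() / max(out.sum(), 1e-12)
    mu03 = (out * (y - cy) ** 3).sum()
    if mu03 < 0:
        out = _transform(flip=True)
    return out


def km_invariant_features(
    img: np.ndarray,
    order: int,
    p: float = 0.5,
    mass_fraction: float = 0.25,
    frame: tuple[int, int] | None = None,
) -> np.ndarray:
    """Translation/rotation/scale-robust Krawtchouk moment features.

    The image is pose-normalized (see :func:`pose_normalize`), brought
    to the reference frame (the image's own shape by default), and its
    Krawtchouk moments at ``order`` are flattened row-major into a
    vector of length ``order**2``.
    """
    img = np.asarray(img, dtype=float)
    if img.sum() <= 0:
        raise ValueError("cannot extract invariant features from a zero-mass image")
    if frame is None:
        frame = img.shape
    canon = pose_normalize(img, mass_fraction=mass_fraction, frame=frame)
    canon = crop_pad(canon, *frame)
    bx = krawtchouk_basis(order, frame[0], p)
    by = krawtchouk_basis(order, frame[1], p)
    return km_moments(canon, bx, by).Q.ravel()
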