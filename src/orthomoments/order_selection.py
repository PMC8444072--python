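"""Reconstruction-error curves over moment orders and order-selection rules.

For Krawtchouk moments the reconstructions at increasing order are
nested orthonormal projections, so the MSE curve is non-increasing and
reaches (numerically) zero at full order.  Pseudo-Zernike curves are
computed with discrete quadrature, so small non-monotonicities are
possible, but the trend is downward on smooth images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .krawtchouk import km_moments, km_reconstruct, krawtchouk_basis
from .pseudozernike import GPZMParams, disk_coordinates, gpzm_moments, weighted_radial

__all__ = ["MSECurve", "mse", "mse_curve", "select_order"]

RULES = ("argmin_mean_mse", "mean_of_argmins")


@dataclass(frozen=True)
class MSECurve:
    """Per-order reconstruction MSE for one image."""

    family: str  # "km" | "gpzm"
    orders: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.orders, self.orders[1:])):
            raise ValueError("orders must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("MSE values must be non-negative")

    def argmin_order(self) -> int:
        """Order attaining the smallest MSE (ties -> smallest order)."""
        return self.orders[int(np.argmin(self.values))]


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared pixel difference."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _km_curve(img: np.ndarray, orders: Sequence[int], p: float) -> list[float]:
    N, M = img.shape
    lmax = max(orders)
    if lmax > min(N, M):
        raise ValueError(f"KM order {lmax} exceeds min image dimension {min(N, M)}")
    bx = krawtchouk_basis(lmax, N, p)
    by = krawtchouk_basis(lmax, M, p)
    Q = bx.K @ img @ by.K.T
    values = []
    for l in orders:
        recon = bx.K[:l].T @ Q[:l, :l] @ by.K[:l]
        values.append(mse(img, recon))
    return values


def _gpzm_curve(img: np.ndarray, orders: Sequence[int], alpha: float) -> list[float]:
    n_max = max(orders)
    zset = gpzm_moments(img, GPZMParams(n_max=n_max, alpha=alpha))
    S = img.shape[0]
    r, theta, mask = disk_coordinates(S)
    rk, tk = r[mask], theta[mask]
    target = img.copy()
    target[~mask] = 0.0
    acc = np.zeros(rk.shape)
    values, want = [], set(orders)
    recon = np.zeros_like(img)
    for n in range(n_max + 1):
        for m in range(n + 1):
            term = zset.Z[n, m] * weighted_radial(n, m, alpha, rk) * np.exp(1j * m * tk)
            acc += term.real if m == 0 else 2.0 * term.real
        if n in want:
            recon[mask] = acc
            values.append(mse(target, recon))
    return values


def mse_curve(
    img: np.ndarray,
    family: str,
    orders: Sequence[int],
    p: float = 0.5,
    alpha: float = 0.0,
) -> MSECurve:
    """Reconstruction MSE of one image over a grid of moment orders.

    For family ``"gpzm"`` the comparison target is the image restricted
    to the inscribed disk (the moments carry no information outside it).
    """
    img = np.asarray(img, dtype=float)
    orders = sorted(set(int(o) for o in orders))
    if not orders:
        raise ValueError("at least one order is required")
    if family == "km":
        values = _km_curve(img, orders, p)
    elif family == "gpzm":
        values = _gpzm_curve(img, orders, alpha)
    else:
        raise ValueError(f"unknown moment family {family!r}")
    return MSECurve(family=family, orders=tuple(orders), values=tuple(values))


def select_order(curves: Sequence[MSECurve], rule: str = "argmin_mean_mse") -> int:
    """Pick a working order from per-image MSE curves.

    ``argmin_mean_mse``
        Order minimizing the across-image mean MSE (ties -> smallest).
    ``mean_of_argmins``
        Mean of the per-image best orders, rounded half away from zero.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("at least one MSE curve is required")
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    grid = curves[0].orders
    if any(c.orders != grid for c in curves):
        raise ValueError("all curves must share the same order grid")
    if rule == "argmin_mean_mse":
        mean = np.mean([c.values for c in curves], axis=0)
        return grid[int(np.argmin(mean))]
    argmins = [c.argmin_order() for c in curves]
    m = float(np.mean(argmins))
    return int(np.floor(m + 0.5)) if m >= 0 else -int(np.floor(-m + 0.5))
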