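"""Beta-posterior estimation of classification accuracy.

Assuming every class is predicted correctly with a single shared
probability pi and a uniform prior on pi, the posterior after observing
``correct`` successes out of ``total`` trials is
``Beta(correct + 1, total - correct + 1)``.  The posterior mean is
``(correct + 1) / (total + 2)`` and credible intervals are equal-tailed
beta quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PosteriorAccuracy",
    "posterior_accuracy",
    "accuracy_from_confusion",
    "coverage_simulation",
]


@dataclass(frozen=True)
class PosteriorAccuracy:
    correct: int
    total: int
    shape_a: float
    shape_b: float
    mean: float
    level: float
    interval: tuple[float, float]

    def format_percent(self) -> str:
        """e.g. ``'94.7% [88.8%, 98.5%]'`` (one decimal, as reported)."""
        lo, hi = self.interval
        return f"{100 * self.mean:.1f}% [{100 * lo:.1f}%, {100 * hi:.1f}%]"


def posterior_accuracy(correct: int, total: int, level: float = 0.95) -> PosteriorAccuracy:
    """Posterior summary of accuracy from correct/total counts."""
    if correct < 0 or total < 0 or correct > total:
        raise ValueError("need 0 <= correct <= total")
    if not 0.0 < level < 1.0:
        raise ValueError("credible level must lie in (0, 1)")
    a, b = correct + 1.0, total - correct + 1.0
    tail = (1.0 - level) / 2.0
    lo, hi = stats.beta.ppf([tail, 1.0 - tail], a, b)
    return PosteriorAccuracy(
        correct=int(correct),
        total=int(total),
        shape_a=a,
        shape_b=b,
        mean=(correct + 1.0) / (total + 2.0),
        level=level,
        interval=(float(lo), float(hi)),
    )


def accuracy_from_confusion(matrix: np.ndarray) -> tuple[int, int]:
    """(correct, total) = (trace, grand sum) of a square count matrix."""
    M = np.asarray(matrix)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0) or not np.all(M == np.round(M)):
        raise ValueError("confusion matrix entries must be non-negative integers")
    return int(np.trace(M)), int(M.sum())


def coverage_simulation(
    pi: float, n: int, reps: int, level: float = 0.95, rng: np.random.Generator | None = None
) -> float:
    """Fraction of simulated binomial datasets whose credible interval covers pi."""
    rng = rng or np.random.default_rng()
    draws = rng.binomial(n, pi, size=reps)
    tail = (1.0 - level) / 2.0
    xs = np.arange(n + 1)
    lo = stats.beta.ppf(tail, xs + 1, n - xs + 1)
    hi = stats.beta.ppf(1.0 - tail, xs + 1, n - xs + 1)
    covered = (lo[draws] <= pi) & (pi <= hi[draws])
    return float(covered.mean())
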