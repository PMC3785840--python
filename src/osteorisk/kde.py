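"""Fixed-bandwidth multivariate kernel density estimation.

Uses the standard (radially symmetric) multivariate normal kernel with one
scalar bandwidth ``h`` shared across all dimensions:

    f(x) = (1 / (n * h**d)) * sum_i K((x - x_i) / h)

Densities are evaluated in log space (shifted-exponential sum), so queries far
from the data underflow smoothly to 0 rather than producing NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp

__all__ = [
    "KdeModel",
    "DegenerateSampleError",
    "gaussian_kernel",
    "kde_evaluate",
    "kde_evaluate_grid",
    "kde_log_evaluate_grid",
    "bandwidth_normal_reference",
    "bandwidth_robust",
]

LOG_2PI = math.log(2.0 * math.pi)


class DegenerateSampleError(ValueError):
    """Raised when a bandwidth rule is applied to a zero-spread sample."""


@dataclass(frozen=True)
class KdeModel:
    """A fitted fixed-bandwidth KDE: training points plus scalar bandwidth."""

    points: np.ndarray  # (n, d)
    h: float

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
            raise ValueError("points must be a non-empty n x d matrix")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        if not self.h > 0:
            raise ValueError(f"bandwidth h must be positive, got {self.h}")
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


def gaussian_kernel(u) -> float:
    """Standard multivariate normal density at ``u``:
    ``(2*pi)**(-d/2) * exp(-||u||**2 / 2)``."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if not np.all(np.isfinite(u)):
        raise ValueError("kernel argument must be finite")
    d = u.size
    return float(math.exp(-0.5 * float(u @ u) - 0.5 * d * LOG_2PI))


def kde_log_evaluate_grid(model: KdeModel, grid) -> np.ndarray:
    """Log-density of the KDE at each row of ``grid`` (vectorized)."""
    X = np.atleast_2d(np.asarray(grid, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(
            f"query dimension {X.shape[1]} != model dimension {model.d}"
        )
    h = model.h
    sq = cdist(X, model.points, "sqeuclidean")
    logk = logsumexp(-sq / (2.0 * h * h), axis=1)
    return logk - math.log(model.n) - model.d * math.log(h) - 0.5 * model.d * LOG_2PI


def kde_evaluate(model: KdeModel, x) -> float:
    """Density estimate at one query point ``x`` (length ``model.d``)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.ndim != 1 or x.size != model.d:
        raise ValueError(f"query must be a vector of length {model.d}")
    return float(np.exp(kde_log_evaluate_grid(model, x[None, :])[0]))


def kde_evaluate_grid(model: KdeModel, grid) -> np.ndarray:
    """Density estimates at each row of ``grid``; elementwise equal to
    :func:`kde_evaluate`."""
    return np.exp(kde_log_evaluate_grid(model, grid))


def _silverman_factor(n: int) -> float:
    return (4.0 / (3.0 * n)) ** 0.2


def bandwidth_normal_reference(values) -> float:
    """Normal-reference bandwidth ``h = (4/(3n))**(1/5) * s`` with ``s`` the
    sample standard deviation (ddof=1).

    Optimal under a normality assumption; oversmooths long-tailed data.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    s = float(np.std(v, ddof=1))
    if s == 0.0:
        raise DegenerateSampleError("sample standard deviation is zero")
    return _silverman_factor(v.size) * s


def bandwidth_robust(values) -> float:
    """MAD-robust bandwidth ``h = (4/(3n))**(1/5) * MAD / 0.6745``.

    ``MAD / 0.6745`` is the median-absolute-deviation estimate of sigma,
    consistent under normality (0.6745 is the upper-quartile z-score); it is
    insensitive to outliers and long tails.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mad = float(np.median(np.abs(v - np.median(v))))
    if mad == 0.0:
        raise DegenerateSampleError("median absolute deviation is zero")
    return _silverman_factor(v.size) * mad / 0.6745
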