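"""Triangular service/length-of-stay distributions and boarding-delay machinery.

The emergency-department (ED) treatment time and the inpatient-unit (IU)
length of stay are both modelled as three-parameter triangular distributions.
The boarding delay seen by a patient blocked from the IU is the time until
the *next* inpatient discharge, i.e. the minimum of the ``c2`` residual
stay times; its mean is obtained by quadrature on the minimum-order-statistic
CDF ``F_min(z) = 1 - prod_i (1 - F_i(z))``.

All quantities are carried internally in hours; loaders convert days to
hours at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "TriangularDist",
    "tri_moments",
    "tri_cdf",
    "min_order_cdf",
    "mean_min",
    "sample",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class TriangularDist:
    """Triangular distribution on ``[lower, upper]`` with mode ``mode`` (hours).

    Frozen/hashable so that derived quantities (e.g. the mean minimum stay
    for a given bed count) can be memoised.
    """

    lower: float
    mode: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"triangular parameters must satisfy 0 <= lower <= mode <= upper, "
                f"got ({self.lower}, {self.mode}, {self.upper})"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.upper == self.lower

    @classmethod
    def from_spec(cls, lower: float, mode: float, upper: float, unit: str = "hours") -> "TriangularDist":
        """Build a distribution from config literals, converting days to hours."""
        if unit in ("hours", "hour", "h"):
            f = 1.0
        elif unit in ("days", "day", "d"):
            f = HOURS_PER_DAY
        else:
            raise ValueError(f"unknown time unit {unit!r}; use 'hours' or 'days'")
        return cls(lower * f, mode * f, upper * f)


@dataclass(frozen=True)
class TriMoments:
    mean: float
    second_moment: float
    variance: float
    scv: float


def tri_moments(dist: TriangularDist) -> TriMoments:
    """Closed-form mean, second moment, variance and SCV of a triangular law.

    mean = (a+m+b)/3 and var = (a^2+m^2+b^2-am-ab-mb)/18; the SCV
    (squared coefficient of variation, var/mean^2) is 0 for a degenerate
    point mass, including the point mass at zero.
    """
    a, m, b = dist.lower, dist.mode, dist.upper
    mean = (a + m + b) / 3.0
    var = (a * a + m * m + b * b - a * m - a * b - m * b) / 18.0
    m2 = var + mean * mean
    scv = var / (mean * mean) if mean > 0 else 0.0
    return TriMoments(mean=mean, second_moment=m2, variance=var, scv=scv)


def tri_cdf(dist: TriangularDist, z):
    """Triangular CDF, vectorised over ``z``."""
    a, m, b = dist.lower, dist.mode, dist.upper
    scalar = np.isscalar(z) or np.ndim(z) == 0
    z = np.atleast_1d(np.asarray(z, dtype=float))
    out = np.zeros_like(z)
    if b == a:
        out = np.where(z >= a, 1.0, 0.0)
        return float(out[0]) if scalar else out
    if m > a:
        left = (z > a) & (z <= m)
        right = (z > m) & (z < b)
        out[left] = (z[left] - a) ** 2 / ((b - a) * (m - a))
    else:  # mode at the lower end: the upper branch covers all of (a, b)
        right = (z > a) & (z < b)
    out[right] = 1.0 - (b - z[right]) ** 2 / ((b - a) * (b - m))
    out[z >= b] = 1.0
    return float(out[0]) if scalar else out


def min_order_cdf(cdf_values: Sequence[float]):
    """CDF of the minimum of independent components evaluated at a common z.

    ``F_min = 1 - prod_i (1 - F_i)``; each value must lie in [0, 1].
    """
    f = np.asarray(cdf_values, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one component CDF value")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("component CDF values must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - f))


def _residual_cdf(dist: TriangularDist):
    """Stationary-residual (equilibrium) CDF of ``dist``.

    F_e(z) = (1/mean) * int_0^z (1 - F(u)) du.  Exposed as the optional
    residual-life reading of the time-to-next-discharge; the default
    pipeline uses the plain CDF.
    """
    mean = tri_moments(dist).mean

    def fe(z: float) -> float:
        z = min(max(float(z), 0.0), dist.upper)
        s, _ = integrate.quad(lambda u: 1.0 - tri_cdf(dist, u), 0.0, z, limit=200)
        return min(max(s / mean, 0.0), 1.0)

    return fe


@lru_cache(maxsize=4096)
def mean_min(dist: TriangularDist, c2: int, residual: bool = False) -> float:
    """Mean of the minimum of ``c2`` iid stay times.

    Computed as ``E[min] = L + int_L^U (1 - F(z))^c2 dz`` (adaptive
    quadrature, absolute tolerance 1e-8 h), where ``F`` is the stay-time
    CDF, or its stationary-residual transform when ``residual=True``
    (then the support lower end is 0).
    """
    if c2 < 1:
        raise ValueError(f"c2 must be >= 1, got {c2}")
    if dist.is_degenerate and not residual:
        return dist.lower
    if residual:
        fe = _residual_cdf(dist)
        lo, hi = 0.0, dist.upper

        def survival_pow(z):
            return (1.0 - fe(z)) ** c2
    else:
        lo, hi = dist.lower, dist.upper

        def survival_pow(z):
            return (1.0 - tri_cdf(dist, z)) ** c2

    val, _ = integrate.quad(
        survival_pow, lo, hi, epsabs=1e-8, epsrel=1e-10, limit=400,
        points=[dist.mode] if lo < dist.mode < hi else None,
    )
    return lo + val


def sample(dist: TriangularDist, n: int, seed=None) -> np.ndarray:
    """``n`` iid triangular draws; identical seed gives an identical stream."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n == 0:
        return np.empty(0)
    if dist.is_degenerate:
        return np.full(n, dist.lower)
    return rng.triangular(dist.lower, dist.mode, dist.upper, size=n)
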