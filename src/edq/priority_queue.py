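"""Multi-priority M/G/c waiting-time approximation chain.

The ED is an M/G/c1 queue with five preemptive-resume priority classes
(class 1 = CTAS level I, highest priority).  No exact analysis exists for
the multi-server multi-priority M/G/c queue, so per-class waits are built
from classical single-server results scaled to c servers:

* Pollaczek-Khinchine mean queueing delay for the FCFS M/G/1 queue,
* a two-moment FCFS M/G/c system-time approximation driven by the Erlang-C
  delay probability,
* the exact preemptive-resume per-class M/G/1 formula,
* the Bondi-style heuristic W_c^k ~ W_c^F * W_1^k / W_1^F that transfers
  the single-server priority structure onto the c-server FCFS estimate.

The composed per-class quantity behaves like a time in system (the M/M/1 and
M/M/c reductions of the building blocks are sojourn times), so results carry
both ``system_time`` (faithful to the printed chain) and
``queueing_delay = max(0, system_time - mean class service time)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClassMoments",
    "WaitEstimates",
    "wq_mg1_fcfs",
    "erlang_c",
    "w_mgc_fcfs",
    "w_mg1_priority",
    "w_mgc_priority",
]


class InstabilityError(ValueError):
    """Raised when an offered load makes the queue non-stationary."""


@dataclass(frozen=True)
class ClassMoments:
    """Per-class arrival rates and (possibly blocking-modified) service moments.

    Class index 0 in the arrays is priority class 1 (highest acuity); the
    optional ``labels`` carry the CTAS names for reporting.
    """

    lam: tuple[float, ...]
    s_mean: tuple[float, ...]
    s_m2: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.lam)
        if k < 1 or len(self.s_mean) != k or len(self.s_m2) != k:
            raise ValueError("lam, s_mean, s_m2 must be equal-length, K >= 1")
        if any(l < 0 for l in self.lam):
            raise ValueError("arrival rates must be non-negative")
        if any(m < 0 for m in self.s_mean):
            raise ValueError("service means must be non-negative")
        for m, m2 in zip(self.s_mean, self.s_m2):
            if m2 < m * m - 1e-12:
                raise ValueError("second moment below squared mean violates Jensen")
        if self.labels and len(self.labels) != k:
            raise ValueError("labels length mismatch")

    @property
    def K(self) -> int:
        return len(self.lam)

    @property
    def lam_total(self) -> float:
        return float(sum(self.lam))

    def aggregate_moments(self) -> tuple[float, float]:
        """Arrival-rate-weighted mixture mean and second moment of service."""
        lt = self.lam_total
        if lt == 0:
            return 0.0, 0.0
        s = sum(l * m for l, m in zip(self.lam, self.s_mean)) / lt
        s2 = sum(l * m2 for l, m2 in zip(self.lam, self.s_m2)) / lt
        return s, s2

    def scaled(self, factor: float) -> "ClassMoments":
        return ClassMoments(
            lam=tuple(l * factor for l in self.lam),
            s_mean=self.s_mean, s_m2=self.s_m2, labels=self.labels,
        )


@dataclass(frozen=True)
class WaitEstimates:
    """Per-class wait estimates (hours) plus chain diagnostics."""

    system_time: tuple[float, ...]
    queueing_delay: tuple[float, ...]
    aggregate_system_time: float
    aggregate_queueing_delay: float
    w1_fcfs: float
    wc_fcfs: float
    p_q: float
    labels: tuple[str, ...] = ()


def wq_mg1_fcfs(lam: float, s_mean: float, s_m2: float) -> float:
    """Pollaczek-Khinchine mean queueing delay of the FCFS M/G/1 queue.

    W = lam * E[S^2] / (2 (1 - rho)), rho = lam * E[S] < 1.
    """
    if lam == 0:
        return 0.0
    rho = lam * s_mean
    if rho >= 1:
        raise InstabilityError(f"M/G/1 load rho={rho:.4f} >= 1")
    return lam * s_m2 / (2.0 * (1.0 - rho))


def erlang_c(c: int, lam: float, s_mean: float) -> float:
    """Erlang-C delay probability of the M/M/c queue (all servers busy).

    Evaluated via the stable Erlang-B recurrence; the geometric tail of the
    defining series is summed in closed form.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if lam == 0 or s_mean == 0:
        return 0.0
    a = lam * s_mean  # offered load in erlangs
    rho = a / c
    if rho >= 1:
        raise InstabilityError(f"M/M/c load rho={rho:.4f} >= 1")
    # Erlang B by recurrence, then C = B / (1 - rho (1 - B))
    b = 1.0
    for j in range(1, c + 1):
        b = a * b / (j + a * b)
    return b / (1.0 - rho * (1.0 - b))


def w_mgc_fcfs(c: int, lam: float, s_mean: float, s_m2: float) -> float:
    """Two-moment FCFS M/G/c system-time approximation.

    W = [S + S * P_Q / (c - lam S)] * (1 + C^2) / 2 with C^2 the service
    SCV and P_Q the Erlang-C delay probability.  Exact for M/M/1 and M/M/c
    sojourn times when C^2 = 1.
    """
    if lam == 0:
        return s_mean * (1.0 + _scv(s_mean, s_m2)) / 2.0 if s_mean else 0.0
    a = lam * s_mean
    if a >= c:
        raise InstabilityError(f"M/G/c load {a:.4f} >= c={c}")
    p_q = erlang_c(c, lam, s_mean)
    c2 = _scv(s_mean, s_m2)
    return (s_mean + s_mean * p_q / (c - a)) * (1.0 + c2) / 2.0


def _scv(s_mean: float, s_m2: float) -> float:
    if s_mean == 0:
        return 0.0
    return s_m2 / (s_mean * s_mean) - 1.0


def w_mg1_priority(classes: ClassMoments) -> tuple[float, ...]:
    """Per-class preemptive-resume M/G/1 mean time in system.

    For class k (1 = highest priority), with rho_k = lam_k * S_k and
    R_k = (1/2) sum_{i<=k} lam_i * E[S_i^2]:

        W_1 = S_1 + R_1/(1 - rho_1)
        W_k = [(1 - sigma_k) S_k + R_k] / [(1 - sigma_{k-1})(1 - sigma_k)]

    where sigma_k = rho_1 + ... + rho_k.  Raises when the cumulative load
    of some class reaches 1, naming the first unstable class.
    """
    rho = [l * m for l, m in zip(classes.lam, classes.s_mean)]
    sigma = np.cumsum(rho)
    for k, sk in enumerate(sigma, start=1):
        if sk >= 1:
            raise InstabilityError(
                f"cumulative load through priority class {k} is {sk:.4f} >= 1"
            )
    out = []
    r = 0.0
    for k in range(classes.K):
        r += 0.5 * classes.lam[k] * classes.s_m2[k]
        s_prev = sigma[k - 1] if k > 0 else 0.0
        s_cur = sigma[k]
        out.append(((1.0 - s_cur) * classes.s_mean[k] + r) / ((1.0 - s_prev) * (1.0 - s_cur)))
    return tuple(out)


def w_mgc_priority(c: int, classes: ClassMoments, scaling: str = "scaled") -> WaitEstimates:
    """Per-class waits in the preemptive-resume M/G/c queue.

    The c-server FCFS estimate is redistributed over priority classes by the
    single-server ratio: W_c^k ~ W_c^F * W_1^k / W_1^F.  Under the default
    ``scaling='scaled'`` the single-server reference system uses all class
    arrival rates divided by c (same class mix and per-server load, stable
    whenever the c-server system is); ``'unscaled'`` uses the raw rates and
    raises when the reference M/G/1 would be unstable.

    ``c == 1`` returns the exact single-server priority formula directly and
    a single class returns the FCFS estimate, bypassing the heuristic ratio.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if scaling not in ("scaled", "unscaled"):
        raise ValueError("scaling must be 'scaled' or 'unscaled'")
    s_agg, s2_agg = classes.aggregate_moments()
    lam = classes.lam_total

    if lam == 0:
        # empty system: no queueing; time in system is the class service time
        return _estimates(classes, tuple(classes.s_mean), 0.0, 0.0, 0.0)

    if lam * s_agg >= c:
        raise InstabilityError(f"aggregate load {lam * s_agg:.4f} >= c={c}")

    if c == 1:
        sys_t = w_mg1_priority(classes)
        w1f = wq_mg1_fcfs(lam, s_agg, s2_agg)
        return _estimates(classes, sys_t, w1f, 0.0, lam * s_agg)

    wcf = w_mgc_fcfs(c, lam, s_agg, s2_agg)
    p_q = erlang_c(c, lam, s_agg)

    if classes.K == 1:
        return _estimates(classes, (wcf,), 0.0, wcf, p_q)

    ref = classes.scaled(1.0 / c) if scaling == "scaled" else classes
    w1k = w_mg1_priority(ref)
    w1f = wq_mg1_fcfs(ref.lam_total, s_agg, s2_agg)
    if w1f == 0.0:
        return _estimates(classes, tuple(classes.s_mean), w1f, wcf, p_q)
    sys_t = tuple(wcf * w / w1f for w in w1k)
    return _estimates(classes, sys_t, w1f, wcf, p_q)


def _estimates(classes: ClassMoments, sys_t, w1f: float, wcf: float, p_q: float) -> WaitEstimates:
    lam = classes.lam_total
    delays = tuple(max(0.0, w - s) for w, s in zip(sys_t, classes.s_mean))
    if lam > 0:
        agg = float(np.dot(classes.lam, sys_t)) / lam
        aggd = float(np.dot(classes.lam, delays)) / lam
    else:
        agg = aggd = 0.0
    return WaitEstimates(
        system_time=tuple(float(x) for x in sys_t),
        queueing_delay=delays,
        aggregate_system_time=agg,
        aggregate_queueing_delay=aggd,
        w1_fcfs=float(w1f),
        wc_fcfs=float(wcf),
        p_q=float(p_q),
        labels=classes.labels,
    )
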