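"""ED-IU coupling: blocking-modified service times and the service-rate fixed point.

A patient who finishes ED treatment but needs an inpatient bed boards in the
ED whenever the IU is full, holding the ED bed until the next inpatient
discharge.  Folding boarding into the ED service time gives the
self-consistency relation

    1/mu = 1/mu_1 + P_b(mu) * mean(min_i T_i),

where mu_1 is the raw ED service rate, P_b the IU blocking probability
(which depends on mu through the transfer rate x * min{lambda, c1*mu}) and
mean(min_i T_i) the expected time to the next of the c2 inpatient
discharges.  Two routes to the fixed point are provided and cross-validated:

* root enumeration of the residual over the provable bracket
  [mu_min, mu_max] (grid scan plus bisection), and
* moment iteration that alternates per-class modified service moments and
  the blocking probability until stationarity.

The converged moments feed the multi-priority wait estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .distributions import TriangularDist, mean_min, tri_moments
from .iu_blocking import BlockingResult, IULoad, blocking_probability, blocking_probability_vec
from .priority_queue import ClassMoments, InstabilityError, WaitEstimates, w_mgc_priority

__all__ = [
    "Scenario",
    "FixedPointResult",
    "SolutionReport",
    "modified_moments",
    "mu_bounds",
    "fixed_point_residual",
    "find_mu_roots",
    "solve",
]

CTAS_LABELS = ("CTAS-I", "CTAS-II", "CTAS-III", "CTAS-IV", "CTAS-V")


@dataclass(frozen=True)
class Scenario:
    """Full parameterization of the coupled ED-IU system (canonical unit: hours).

    ``arrival_rates`` are per priority class, highest acuity first
    (CTAS I..V for the standard five-class system).  ``transfer_fraction``
    is the proportion x of ED patients admitted to the IU,
    ``lambda_direct`` the direct-to-IU arrival rate.  ``ed_service`` is the
    shared raw ED treatment-time distribution; ``ed_service_per_class``
    optionally overrides it class by class.
    """

    arrival_rates: tuple[float, ...]
    lambda_direct: float
    transfer_fraction: float
    ed_service: TriangularDist
    iu_los: TriangularDist
    c1: int
    c2: int
    ed_service_per_class: Optional[tuple[TriangularDist, ...]] = None
    wait_metric: str = "queueing_delay"
    bondi_scaling: str = "scaled"
    residual_los: bool = False
    labels: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.arrival_rates) < 1:
            raise ValueError("need at least one priority class")
        if any(l < 0 for l in self.arrival_rates):
            raise ValueError("arrival rates must be non-negative")
        if self.lambda_direct < 0:
            raise ValueError("lambda_direct must be non-negative")
        if not 0.0 <= self.transfer_fraction <= 1.0:
            raise ValueError("transfer_fraction must lie in [0, 1]")
        if self.c1 < 1 or self.c2 < 1:
            raise ValueError("bed counts must be >= 1")
        if self.wait_metric not in ("queueing_delay", "system_time"):
            raise ValueError("wait_metric must be 'queueing_delay' or 'system_time'")
        if self.bondi_scaling not in ("scaled", "unscaled"):
            raise ValueError("bondi_scaling must be 'scaled' or 'unscaled'")
        if self.ed_service_per_class is not None and len(self.ed_service_per_class) != self.K:
            raise ValueError("ed_service_per_class length mismatch")
        if self.labels and len(self.labels) != self.K:
            raise ValueError("labels length mismatch")

    @property
    def K(self) -> int:
        return len(self.arrival_rates)

    @property
    def lam_total(self) -> float:
        return float(sum(self.arrival_rates))

    @property
    def class_labels(self) -> tuple[str, ...]:
        if self.labels:
            return self.labels
        if self.K == 5:
            return CTAS_LABELS
        return tuple(f"class-{k+1}" for k in range(self.K))

    def class_dists(self) -> tuple[TriangularDist, ...]:
        if self.ed_service_per_class is not None:
            return self.ed_service_per_class
        return tuple(self.ed_service for _ in range(self.K))

    def raw_moments(self) -> ClassMoments:
        """Raw (uncoupled) per-class ED service moments."""
        ms = [tri_moments(d) for d in self.class_dists()]
        return ClassMoments(
            lam=tuple(self.arrival_rates),
            s_mean=tuple(m.mean for m in ms),
            s_m2=tuple(m.second_moment for m in ms),
            labels=self.class_labels,
        )

    @property
    def mu1(self) -> float:
        """Raw aggregate ED service rate 1/(sum_k q_k S_k)."""
        s, _ = self.raw_moments().aggregate_moments()
        if s == 0:
            raise ValueError("zero mean service time")
        return 1.0 / s

    @property
    def mu_I(self) -> float:
        """IU service (discharge) rate, 1/mean length of stay."""
        return 1.0 / tri_moments(self.iu_los).mean

    @property
    def iu_scv(self) -> float:
        return tri_moments(self.iu_los).scv

    def boarding_mean(self) -> float:
        """Expected time to the next inpatient discharge, mean(min_i T_i)."""
        return mean_min(self.iu_los, self.c2, residual=self.residual_los)

    def iu_load(self, transfer_rate: float) -> IULoad:
        return IULoad(
            c2=self.c2, mu_I=self.mu_I,
            lambda_transfer=transfer_rate,
            lambda_direct=self.lambda_direct,
            scv_service=self.iu_scv,
        )

    def blocking_at(self, mu: float) -> BlockingResult:
        """Blocking probability with transfer rate x * min{lambda, c1*mu}."""
        r_d = min(self.lam_total, self.c1 * mu)
        return blocking_probability(self.iu_load(self.transfer_fraction * r_d))


@dataclass(frozen=True)
class FixedPointResult:
    mu_min: float
    mu_max: float
    roots: tuple[float, ...]
    residuals: tuple[float, ...]
    mu_hat_min: Optional[float]
    mu_hat_max: Optional[float]
    sufficient_met: bool
    necessary_met: bool
    necessary_and_sufficient_exists: bool
    status: str  # "ok" | "no_root"


@dataclass(frozen=True)
class SolutionReport:
    scenario: Scenario
    fixed_point: FixedPointResult
    p_b: BlockingResult
    modified_moments: ClassMoments
    mu_hat: float
    waits: Optional[WaitEstimates]
    converged: bool
    iterations: int
    status: str  # "ok" | "no_solution" | "unstable"

    def class_waits(self, metric: Optional[str] = None) -> tuple[float, ...]:
        """Per-class waits under the scenario's (or an explicit) metric."""
        if self.waits is None:
            raise ValueError(f"no wait estimates (status={self.status})")
        metric = metric or self.scenario.wait_metric
        if metric == "system_time":
            return self.waits.system_time
        return self.waits.queueing_delay

    def aggregate_wait(self, metric: Optional[str] = None) -> float:
        w = self.class_waits(metric)
        lam = self.scenario.arrival_rates
        return float(np.dot(lam, w) / sum(lam))


def modified_moments(raw_mean: float, raw_m2: float, p_b: float, boarding_mean: float) -> tuple[float, float]:
    """Blocking-modified service moments.

    The boarding term enters as the deterministic shift p_b * boarding_mean:
    mean' = mean + p_b*B, m2' = m2 + 2*mean*p_b*B + (p_b*B)^2.
    """
    if raw_mean < 0 or raw_m2 < raw_mean * raw_mean - 1e-12 or p_b < 0 or boarding_mean < 0:
        raise ValueError("invalid inputs to modified_moments")
    shift = p_b * boarding_mean
    return raw_mean + shift, raw_m2 + 2.0 * raw_mean * shift + shift * shift


def mu_bounds(scenario: Scenario) -> tuple[float, float]:
    """Provable bracket for the effective ED service rate.

    mu_max = mu_1 (never blocked); mu_min = 1/(1/mu_1 + mean(min_i T_i))
    (always blocked).
    """
    mu1 = scenario.mu1
    bm = scenario.boarding_mean()
    return 1.0 / (1.0 / mu1 + bm), mu1


def fixed_point_residual(mu: float, scenario: Scenario) -> float:
    """Residual 1/mu - P_b(mu)*mean(min T) - 1/mu_1 of the coupling equation."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    pb = scenario.blocking_at(mu).p_b
    return 1.0 / mu - pb * scenario.boarding_mean() - 1.0 / scenario.mu1


_RESIDUAL_TOL = 1e-10  # hours; |residual| below this counts as a root


def find_mu_roots(scenario: Scenario, grid_n: int = 512, tol: float = 1e-9) -> FixedPointResult:
    """Enumerate fixed points of the coupling equation over [mu_min, mu_max].

    The residual is evaluated on a uniform grid; every sign-change bracket is
    bisected (Brent) to |residual| < 1e-10 h, and near-zero grid points are
    accepted directly.  Feasibility verdicts follow the steady-state
    conditions: sufficient uses the smallest root, necessary the largest,
    and a necessary-and-sufficient condition exists when they coincide
    within ``tol``.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    mu_min, mu_max = mu_bounds(scenario)
    grid = np.linspace(mu_min, mu_max, grid_n)
    r_d = np.minimum(scenario.lam_total, scenario.c1 * grid)
    pb = blocking_probability_vec(
        scenario.c2, scenario.mu_I,
        scenario.transfer_fraction * r_d + scenario.lambda_direct,
        scenario.iu_scv,
    )
    res = 1.0 / grid - pb * scenario.boarding_mean() - 1.0 / scenario.mu1

    roots: list[float] = []
    for i, (m, r) in enumerate(zip(grid, res)):
        if abs(r) < _RESIDUAL_TOL:
            roots.append(float(m))
    for i in range(grid_n - 1):
        r0, r1 = res[i], res[i + 1]
        if abs(r0) < _RESIDUAL_TOL or abs(r1) < _RESIDUAL_TOL:
            continue
        if r0 * r1 < 0:
            root = brentq(
                fixed_point_residual, grid[i], grid[i + 1], args=(scenario,),
                xtol=1e-14, rtol=8.9e-16, maxiter=200,
            )
            roots.append(float(root))

    # deduplicate near-identical roots
    roots.sort()
    dedup: list[float] = []
    for r in roots:
        if not dedup or abs(r - dedup[-1]) > 1e-12 * max(1.0, abs(r)):
            dedup.append(r)
    residuals = tuple(fixed_point_residual(r, scenario) for r in dedup)

    if not dedup:
        return FixedPointResult(
            mu_min=mu_min, mu_max=mu_max, roots=(), residuals=(),
            mu_hat_min=None, mu_hat_max=None,
            sufficient_met=False, necessary_met=False,
            necessary_and_sufficient_exists=False, status="no_root",
        )

    mu_hat_min, mu_hat_max = dedup[0], dedup[-1]
    lam = scenario.lam_total
    x, lam_d = scenario.transfer_fraction, scenario.lambda_direct
    c1, c2, mu_i = scenario.c1, scenario.c2, scenario.mu_I

    def _feasible(mu_hat: float) -> bool:
        return (lam <= c1 * mu_hat) and (x * min(lam, c1 * mu_hat) + lam_d <= c2 * mu_i)

    return FixedPointResult(
        mu_min=mu_min, mu_max=mu_max,
        roots=tuple(dedup), residuals=residuals,
        mu_hat_min=mu_hat_min, mu_hat_max=mu_hat_max,
        sufficient_met=_feasible(mu_hat_min),
        necessary_met=_feasible(mu_hat_max),
        necessary_and_sufficient_exists=abs(mu_hat_max - mu_hat_min) <= tol,
        status="ok",
    )


_ITER_TOL = 1e-8  # hours, on the max per-class modified-mean change
_MAX_ITER = 1000


def _mu_of_pb(scenario: Scenario, raw: ClassMoments, pb: float, bm: float) -> float:
    q = np.asarray(raw.lam) / raw.lam_total
    means = np.array([modified_moments(m, m2, pb, bm)[0] for m, m2 in zip(raw.s_mean, raw.s_m2)])
    return 1.0 / float(q @ means)


def _iterate_moments(scenario: Scenario, damping: float = 0.0) -> tuple[ClassMoments, BlockingResult, float, int, bool]:
    """Moment iteration: alternate modified moments and blocking probability.

    Starting from P_b = 0, each pass computes the per-class modified
    moments, the aggregate service rate mu = 1/(sum_k q_k S_k), the
    transfer rate x*min{lambda, c1*mu} and the new blocking probability.
    Convergence is declared when the fixed-point gap |P_b' - P_b| times the
    boarding mean (i.e. the induced change in every modified service mean)
    drops below 1e-8 h.  ``damping`` blends updates,
    p <- (1-d) p_new + d p_old, to tame the steep blocking knee.
    """
    raw = scenario.raw_moments()
    bm = scenario.boarding_mean()
    pb = 0.0
    pb_result = None
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        mu = _mu_of_pb(scenario, raw, pb, bm)
        pb_result = scenario.blocking_at(mu)
        gap = abs(pb_result.p_b - pb) * bm
        if gap < _ITER_TOL:
            pb = pb_result.p_b
            converged = True
            break
        pb = (1.0 - damping) * pb_result.p_b + damping * pb
    return _finalize(scenario, raw, pb, bm, pb_result, it, converged)


def _bisect_pb(scenario: Scenario, raw: ClassMoments, bm: float) -> tuple[ClassMoments, BlockingResult, float, int, bool]:
    """Guaranteed fallback: bisection on g(p) = P_b(mu(p)) - p.

    g(0) >= 0 and g(1) <= 0 always, so a consistent blocking probability
    exists even where the plain iteration cycles across the blocking knee.
    """
    lo, hi = 0.0, 1.0
    pb = 0.5
    pb_result = None
    it = 0
    for it in range(1, 200 + 1):
        pb = 0.5 * (lo + hi)
        mu = _mu_of_pb(scenario, raw, pb, bm)
        pb_result = scenario.blocking_at(mu)
        g = pb_result.p_b - pb
        if abs(g) * bm < _ITER_TOL or (hi - lo) * bm < 1e-14:
            return _finalize(scenario, raw, pb_result.p_b, bm, pb_result, it, True)
        if g > 0:
            lo = pb
        else:
            hi = pb
    return _finalize(scenario, raw, pb, bm, pb_result, it, False)


def _finalize(scenario, raw, pb, bm, pb_result, it, converged):
    moments = ClassMoments(
        lam=raw.lam,
        s_mean=tuple(modified_moments(m, m2, pb, bm)[0] for m, m2 in zip(raw.s_mean, raw.s_m2)),
        s_m2=tuple(modified_moments(m, m2, pb, bm)[1] for m, m2 in zip(raw.s_mean, raw.s_m2)),
        labels=raw.labels,
    )
    s_agg, _ = moments.aggregate_moments()
    if pb_result is None:
        pb_result = scenario.blocking_at(1.0 / s_agg)
    return moments, pb_result, 1.0 / s_agg, it, converged


def solve(scenario: Scenario, grid_n: int = 512) -> SolutionReport:
    """Full analytic solve of the coupled system.

    Runs the moment iteration (with a damped retry on oscillation), the root
    enumeration for feasibility reporting, and the multi-priority wait
    estimates on the converged moments.  ``status`` is ``"unstable"`` when
    the ED load exceeds capacity at the converged service rate,
    ``"no_solution"`` when the iteration fails to settle.
    """
    if scenario.lam_total <= 0:
        raise ValueError("total ED arrival rate must be positive for a solve")
    fp = find_mu_roots(scenario, grid_n=grid_n)

    moments, pb_result, mu_hat, iters, converged = _iterate_moments(scenario)
    for damping in (0.5, 0.9):  # retried on oscillation with heavier smoothing
        if converged:
            break
        moments, pb_result, mu_hat, it2, converged = _iterate_moments(scenario, damping=damping)
        iters += it2
    if not converged:
        # the blocking knee can be too steep for damped iteration; fall back
        # to bisection on the self-consistent blocking probability
        moments, pb_result, mu_hat, it2, converged = _bisect_pb(
            scenario, scenario.raw_moments(), scenario.boarding_mean())
        iters += it2
    if not converged:
        return SolutionReport(
            scenario=scenario, fixed_point=fp, p_b=pb_result,
            modified_moments=moments, mu_hat=mu_hat, waits=None,
            converged=False, iterations=iters, status="no_solution",
        )

    if scenario.lam_total >= scenario.c1 * mu_hat:
        return SolutionReport(
            scenario=scenario, fixed_point=fp, p_b=pb_result,
            modified_moments=moments, mu_hat=mu_hat, waits=None,
            converged=True, iterations=iters, status="unstable",
        )

    try:
        waits = w_mgc_priority(scenario.c1, moments, scaling=scenario.bondi_scaling)
    except InstabilityError:
        return SolutionReport(
            scenario=scenario, fixed_point=fp, p_b=pb_result,
            modified_moments=moments, mu_hat=mu_hat, waits=None,
            converged=True, iterations=iters, status="unstable",
        )
    return SolutionReport(
        scenario=scenario, fixed_point=fp, p_b=pb_result,
        modified_moments=moments, mu_hat=mu_hat, waits=waits,
        converged=True, iterations=iters, status="ok",
    )
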