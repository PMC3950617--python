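"""Fast-track variant: an express ED line for low-acuity patients.

The ED bed pool is split into an express line serving CTAS IV-V and a
regular line serving CTAS I-III.  Both lines feed the same inpatient unit,
so they share one blocking probability whose transfer flow sums the two
lines' contributions; the joint fixed point is found by iterating the
blocking-modified moments of both lines against the shared IU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .coupling import (
    Scenario,
    SolutionReport,
    find_mu_roots,
    modified_moments,
)
from .iu_blocking import BlockingResult, blocking_probability
from .priority_queue import ClassMoments, InstabilityError, w_mgc_priority

__all__ = ["FastTrackConfig", "FastTrackSolution", "split_scenario", "solve_fast_track"]

_FAST_CLASSES = (3, 4)  # CTAS IV and V (0-based indices in the 5-class system)
_REGULAR_CLASSES = (0, 1, 2)


@dataclass(frozen=True)
class FastTrackConfig:
    """Fast-track split: fraction of ED beds carved out for the express line.

    ``literal_eq14`` splits the raw ED service rate between the lines in
    proportion to bed share (each line's service slows down accordingly);
    the default keeps the base service-time distribution on both lines.
    Per-line transfer fractions may override the scenario's shared value.
    """

    fraction_fast: float
    literal_eq14: bool = False
    transfer_fraction_fast: Optional[float] = None
    transfer_fraction_regular: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_fast < 1.0:
            raise ValueError("fraction_fast must lie strictly in (0, 1)")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _subset_scenario(scenario: Scenario, idx: Sequence[int], c1: int, name: str) -> Scenario:
    dists = scenario.class_dists()
    return replace(
        scenario,
        arrival_rates=tuple(scenario.arrival_rates[i] for i in idx),
        ed_service_per_class=tuple(dists[i] for i in idx),
        labels=tuple(scenario.class_labels[i] for i in idx),
        c1=c1,
        name=name,
    )


def split_scenario(scenario: Scenario, config: FastTrackConfig) -> tuple[Scenario, Scenario]:
    """Split a five-class scenario into (fast, regular) line scenarios.

    The fast line receives CTAS IV-V on ``round(fraction_fast * c1)`` beds
    (round half away from zero, clamped so each line keeps >= 1 bed); the
    regular line receives CTAS I-III and the remaining beds.  Both inherit
    the IU parameters.
    """
    if scenario.K != 5:
        raise ValueError("fast-track split is defined for the five-class CTAS system")
    if scenario.c1 < 2:
        raise ValueError("need at least 2 ED beds to split into two lines")
    n_fast = _round_half_away(config.fraction_fast * scenario.c1)
    n_fast = max(1, min(scenario.c1 - 1, n_fast))
    if n_fast < 1 or scenario.c1 - n_fast < 1:
        raise ValueError("fast-track fraction leaves a line with no beds")
    fast = _subset_scenario(scenario, _FAST_CLASSES, n_fast, name="fast-track")
    regular = _subset_scenario(scenario, _REGULAR_CLASSES, scenario.c1 - n_fast, name="regular-line")
    if config.transfer_fraction_fast is not None:
        fast = replace(fast, transfer_fraction=config.transfer_fraction_fast)
    if config.transfer_fraction_regular is not None:
        regular = replace(regular, transfer_fraction=config.transfer_fraction_regular)
    if config.literal_eq14:
        # slow each line so the line service *rates* sum to the base rate
        fast = _slow_down(fast, scenario.c1 / n_fast)
        regular = _slow_down(regular, scenario.c1 / (scenario.c1 - n_fast))
    return fast, regular


def _slow_down(scenario: Scenario, factor: float) -> Scenario:
    dists = tuple(
        type(d)(d.lower * factor, d.mode * factor, d.upper * factor)
        for d in scenario.class_dists()
    )
    return replace(scenario, ed_service_per_class=dists)


@dataclass(frozen=True)
class FastTrackSolution:
    fast_line: SolutionReport
    regular_line: SolutionReport
    p_b: BlockingResult
    weight_regular: float  # P_r^I: share of arrivals on the regular line
    weight_fast: float     # P_r^II
    aggregate_wait: float
    aggregate_system_time: float
    converged: bool
    iterations: int
    status: str  # "ok" | "no_solution" | "unstable:<line>"


_ITER_TOL = 1e-8
_MAX_ITER = 1000


def _solve_lines(lines: Sequence[Scenario], base: Scenario) -> tuple[list[ClassMoments], BlockingResult, list[float], int, bool]:
    """Joint moment iteration for ED lines sharing one inpatient unit.

    The shared blocking probability is driven by the summed transfer flow
    x_l * min{lambda_l, c1_l * mu_l} of every line plus the direct stream.
    """
    raws = [s.raw_moments() for s in lines]
    bm = base.boarding_mean()
    pb = 0.0
    pb_result = None
    prev = [np.array(r.s_mean) for r in raws]
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        transfer = 0.0
        means_all = []
        for s, raw in zip(lines, raws):
            means = np.array([modified_moments(m, m2, pb, bm)[0] for m, m2 in zip(raw.s_mean, raw.s_m2)])
            q = np.array(raw.lam) / raw.lam_total
            mu_line = 1.0 / float(q @ means)
            transfer += s.transfer_fraction * min(raw.lam_total, s.c1 * mu_line)
            means_all.append(means)
        pb_result = blocking_probability(base.iu_load(transfer))
        pb = pb_result.p_b
        delta = max(float(np.max(np.abs(m - p))) for m, p in zip(means_all, prev))
        prev = means_all
        if delta < _ITER_TOL and it > 1:
            converged = True
            break
    moments = [
        ClassMoments(
            lam=raw.lam,
            s_mean=tuple(modified_moments(m, m2, pb, bm)[0] for m, m2 in zip(raw.s_mean, raw.s_m2)),
            s_m2=tuple(modified_moments(m, m2, pb, bm)[1] for m, m2 in zip(raw.s_mean, raw.s_m2)),
            labels=raw.labels,
        )
        for raw in raws
    ]
    mu_hats = [1.0 / m.aggregate_moments()[0] for m in moments]
    return moments, pb_result, mu_hats, it, converged


def _line_report(scenario: Scenario, moments: ClassMoments, pb: BlockingResult,
                 mu_hat: float, iterations: int, converged: bool) -> SolutionReport:
    fp = find_mu_roots(scenario)
    if not converged:
        status, waits = "no_solution", None
    elif scenario.lam_total >= scenario.c1 * mu_hat:
        status, waits = "unstable", None
    else:
        try:
            waits = w_mgc_priority(scenario.c1, moments, scaling=scenario.bondi_scaling)
            status = "ok"
        except InstabilityError:
            status, waits = "unstable", None
    return SolutionReport(
        scenario=scenario, fixed_point=fp, p_b=pb, modified_moments=moments,
        mu_hat=mu_hat, waits=waits, converged=converged,
        iterations=iterations, status=status,
    )


def solve_fast_track(scenario: Scenario, config: FastTrackConfig) -> FastTrackSolution:
    """Solve the two-line fast-track system with its shared IU fixed point.

    Returns per-line reports plus the arrival-share-weighted aggregate wait
    (weights P_r^I = regular share, P_r^II = fast share of ED arrivals).
    """
    fast, regular = split_scenario(scenario, config)
    moments, pb, mu_hats, iters, converged = _solve_lines([fast, regular], scenario)
    fast_rep = _line_report(fast, moments[0], pb, mu_hats[0], iters, converged)
    reg_rep = _line_report(regular, moments[1], pb, mu_hats[1], iters, converged)

    lam_f, lam_r = fast.lam_total, regular.lam_total
    w_fast = lam_f / (lam_f + lam_r)
    w_reg = 1.0 - w_fast

    if not converged:
        status = "no_solution"
    elif fast_rep.status != "ok":
        status = f"unstable:{fast.name}" if fast_rep.status == "unstable" else fast_rep.status
    elif reg_rep.status != "ok":
        status = f"unstable:{regular.name}" if reg_rep.status == "unstable" else reg_rep.status
    else:
        status = "ok"

    if status == "ok":
        agg = w_reg * reg_rep.aggregate_wait() + w_fast * fast_rep.aggregate_wait()
        agg_sys = (
            w_reg * reg_rep.aggregate_wait("system_time")
            + w_fast * fast_rep.aggregate_wait("system_time")
        )
    else:
        agg = agg_sys = float("nan")

    return FastTrackSolution(
        fast_line=fast_rep, regular_line=reg_rep, p_b=pb,
        weight_regular=w_reg, weight_fast=w_fast,
        aggregate_wait=agg, aggregate_system_time=agg_sys,
        converged=converged, iterations=iters, status=status,
    )
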