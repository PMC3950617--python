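"""Discrete-event simulation of the tandem ED -> IU patient-flow system.

Event-driven Monte-Carlo model used to validate the analytic
approximations: Poisson arrivals per priority class, ``c1`` ED beds with
preemptive-resume priority scheduling, an ``x`` chance of needing an
inpatient bed on ED completion, boarding in the ED bed when the IU is full
(boarders served FCFS at the next discharge and are not preemptible), and
direct IU arrivals that are lost when the IU is full.

Statistics are collected per replication after a warmup period and
aggregated across independent replications with t-based 95% confidence
intervals.  The same seed reproduces results bit for bit.
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .coupling import Scenario, solve

__all__ = ["SimConfig", "SimResult", "simulate", "compare_analytic_sim"]

# event codes (heap tuples sort by time, then sequence number)
_ARRIVAL, _COMPLETE, _IU_DEPART, _DIRECT = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Replication design: horizon and warmup in hours."""

    horizon: float = 2000.0
    warmup: float = 200.0
    replications: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.warmup < self.horizon:
            raise ValueError("need 0 <= warmup < horizon")
        if self.replications < 1:
            raise ValueError("need at least one replication")


@dataclass(frozen=True)
class SimResult:
    labels: tuple[str, ...]
    delay_mean: tuple[float, ...]
    delay_ci_half: tuple[float, ...]
    system_mean: tuple[float, ...]
    system_ci_half: tuple[float, ...]
    aggregate_delay: float
    aggregate_system: float
    aggregate_delay_ci_half: float
    aggregate_system_ci_half: float
    blocking_mean: float
    blocking_ci_half: float
    iu_attempts_total: int
    ed_utilization: float
    iu_utilization: float
    preemptions_per_hour: float
    little_l: tuple[float, ...]
    little_lambda_w: tuple[float, ...]
    replications: int
    horizon: float
    warmup: float


class _Patient:
    __slots__ = ("cls", "t_arr", "remaining", "seg_start", "token",
                 "first_start", "needs_iu")

    def __init__(self, cls: int, t_arr: float, service: float, needs_iu: bool):
        self.cls = cls
        self.t_arr = t_arr
        self.remaining = service
        self.seg_start = 0.0
        self.token = 0
        self.first_start = -1.0
        self.needs_iu = needs_iu


def _gen_poisson_times(rng: np.random.Generator, rate: float, horizon: float) -> np.ndarray:
    if rate <= 0:
        return np.empty(0)
    n = int(rate * horizon * 1.25 + 10 * math.sqrt(rate * horizon + 1.0)) + 10
    t = np.cumsum(rng.exponential(1.0 / rate, size=n))
    while t.size and t[-1] < horizon:
        t = np.concatenate([t, t[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n))])
    return t[t < horizon]


class _Pool:
    """Lazily refilled pool of iid draws (keeps per-event RNG cost amortised)."""

    def __init__(self, rng: np.random.Generator, draw: Callable[[np.random.Generator, int], np.ndarray]):
        self._rng = rng
        self._draw = draw
        self._buf = draw(rng, 256)
        self._i = 0

    def next(self) -> float:
        if self._i >= self._buf.size:
            self._buf = self._draw(self._rng, 2 * self._buf.size)
            self._i = 0
        v = self._buf[self._i]
        self._i += 1
        return float(v)


def _run_replication(scenario: Scenario, horizon: float, warmup: float,
                     rng: np.random.Generator,
                     ed_sampler: Optional[Callable] = None,
                     iu_sampler: Optional[Callable] = None) -> dict:
    K = scenario.K
    c1, c2 = scenario.c1, scenario.c2
    x = scenario.transfer_fraction
    dists = scenario.class_dists()

    if ed_sampler is None:
        def ed_sampler(rng_, size, k=None):  # noqa: F811 - default sampler
            d = dists[k]
            if d.is_degenerate:
                return np.full(size, d.lower)
            return rng_.triangular(d.lower, d.mode, d.upper, size)
    if iu_sampler is None:
        def iu_sampler(rng_, size):  # noqa: F811
            d = scenario.iu_los
            if d.is_degenerate:
                return np.full(size, d.lower)
            return rng_.triangular(d.lower, d.mode, d.upper, size)

    heap: list[tuple] = []
    seq = 0

    # pre-generate arrivals, service requirements and admission flags per class
    for k in range(K):
        times = _gen_poisson_times(rng, scenario.arrival_rates[k], horizon)
        if times.size == 0:
            continue
        services = np.asarray(ed_sampler(rng, times.size, k=k), dtype=float)
        needs = rng.random(times.size) < x
        for t, s, nd in zip(times, services, needs):
            heapq.heappush(heap, (t, seq, _ARRIVAL, _Patient(k, t, s, bool(nd))))
            seq += 1
    for t in _gen_poisson_times(rng, scenario.lambda_direct, horizon):
        heapq.heappush(heap, (t, seq, _DIRECT, None))
        seq += 1

    los_pool = _Pool(rng, iu_sampler)

    in_service: list[_Patient] = []
    queues: list[list] = [[] for _ in range(K)]  # heaps of (t_arr, seq, patient)
    boarders: deque[_Patient] = deque()
    iu_busy = 0
    qseq = 0

    # counters (collected after warmup)
    delays = [[] for _ in range(K)]
    systems = [[] for _ in range(K)]
    iu_attempts = 0
    iu_blocked = 0
    preemptions = 0
    ed_busy_area = 0.0
    iu_busy_area = 0.0
    ed_sys_area = 0.0
    last_t = warmup
    n_ed_sys = 0  # waiting + in service + boarding
    arrivals_after_warmup = [0] * K

    def account(now: float) -> None:
        nonlocal ed_busy_area, iu_busy_area, ed_sys_area, last_t
        if now > last_t:
            dt = now - last_t
            ed_busy_area += dt * (len(in_service) + len(boarders))
            iu_busy_area += dt * iu_busy
            ed_sys_area += dt * n_ed_sys
            last_t = now

    def start_service(p: _Patient, now: float) -> None:
        nonlocal seq
        p.seg_start = now
        if p.first_start < 0:
            p.first_start = now
            if p.t_arr >= warmup:
                delays[p.cls].append(now - p.t_arr)
        in_service.append(p)
        heapq.heappush(heap, (now + p.remaining, seq, _COMPLETE, (p, p.token)))
        seq += 1

    def next_from_queue(now: float) -> None:
        for k in range(K):
            if queues[k]:
                _, _, p = heapq.heappop(queues[k])
                start_service(p, now)
                return

    def release_bed(p: _Patient, now: float) -> None:
        nonlocal n_ed_sys
        if p.t_arr >= warmup:
            systems[p.cls].append(now - p.t_arr)
        n_ed_sys -= 1
        next_from_queue(now)

    def enter_iu(now: float) -> None:
        nonlocal iu_busy, seq
        iu_busy += 1
        heapq.heappush(heap, (now + los_pool.next(), seq, _IU_DEPART, None))
        seq += 1

    while heap:
        t, _, code, data = heapq.heappop(heap)
        if t > horizon:
            break
        if t >= warmup:
            account(t)

        if code == _ARRIVAL:
            p = data
            n_ed_sys += 1
            if p.t_arr >= warmup:
                arrivals_after_warmup[p.cls] += 1
            if len(in_service) + len(boarders) < c1:
                start_service(p, t)
            else:
                victim = None
                for q in in_service:
                    if q.cls > p.cls and (victim is None or (q.cls, q.seg_start) > (victim.cls, victim.seg_start)):
                        victim = q
                if victim is not None:
                    # preemptive resume: victim keeps its remaining work
                    victim.remaining -= t - victim.seg_start
                    victim.token += 1
                    in_service.remove(victim)
                    heapq.heappush(queues[victim.cls], (victim.t_arr, qseq, victim))
                    qseq += 1
                    if t >= warmup:
                        preemptions += 1
                    start_service(p, t)
                else:
                    heapq.heappush(queues[p.cls], (p.t_arr, qseq, p))
                    qseq += 1

        elif code == _COMPLETE:
            p, token = data
            if token != p.token:
                continue  # stale event from before a preemption
            in_service.remove(p)
            if p.needs_iu:
                if t >= warmup:
                    iu_attempts += 1
                if iu_busy < c2:
                    enter_iu(t)
                    release_bed(p, t)
                else:
                    if t >= warmup:
                        iu_blocked += 1
                    boarders.append(p)  # holds the ED bed, not preemptible
            else:
                release_bed(p, t)

        elif code == _IU_DEPART:
            iu_busy -= 1
            if boarders:
                p = boarders.popleft()
                enter_iu(t)
                release_bed(p, t)

        else:  # direct IU arrival; lost if the unit is full
            if t >= warmup:
                iu_attempts += 1
            if iu_busy < c2:
                enter_iu(t)
            elif t >= warmup:
                iu_blocked += 1

    account(horizon)
    span = horizon - warmup
    return {
        "delay": [float(np.mean(d)) if d else 0.0 for d in delays],
        "system": [float(np.mean(s)) if s else 0.0 for s in systems],
        "n_delay": [len(d) for d in delays],
        "n_system": [len(s) for s in systems],
        "blocking": (iu_blocked / iu_attempts) if iu_attempts else 0.0,
        "iu_attempts": iu_attempts,
        "ed_util": ed_busy_area / (span * c1),
        "iu_util": iu_busy_area / (span * c2),
        "preempt_rate": preemptions / span,
        "l_ed": ed_sys_area / span,
        "lam_obs": [n / span for n in arrivals_after_warmup],
    }


def _ci_half(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return 0.0
    from scipy.stats import t as tdist

    return float(tdist.ppf(0.975, n - 1) * values.std(ddof=1) / math.sqrt(n))


def simulate(scenario: Scenario, config: SimConfig,
             ed_sampler: Optional[Callable] = None,
             iu_sampler: Optional[Callable] = None) -> SimResult:
    """Replicated discrete-event simulation of the coupled system.

    ``ed_sampler(rng, size, k=class)`` / ``iu_sampler(rng, size)`` override
    the triangular service and stay-time laws (used e.g. to validate
    against exact exponential benchmarks).  Overloaded configurations run
    and report truncated-horizon statistics rather than crashing.
    """
    K = scenario.K
    children = np.random.SeedSequence(config.seed).spawn(config.replications)
    reps = [
        _run_replication(scenario, config.horizon, config.warmup,
                         np.random.default_rng(ss), ed_sampler, iu_sampler)
        for ss in children
    ]
    delay = np.array([r["delay"] for r in reps])
    system = np.array([r["system"] for r in reps])
    blocking = np.array([r["blocking"] for r in reps])
    lam_obs = np.array([r["lam_obs"] for r in reps])

    lam_tot = lam_obs.sum(axis=1).mean()
    if lam_tot > 0:
        w = lam_obs.mean(axis=0) / lam_obs.mean(axis=0).sum()
        agg_delay_reps = delay @ w
        agg_system_reps = system @ w
        agg_delay = float(agg_delay_reps.mean())
        agg_system = float(agg_system_reps.mean())
        agg_delay_ci = _ci_half(agg_delay_reps)
        agg_system_ci = _ci_half(agg_system_reps)
    else:
        agg_delay = agg_system = agg_delay_ci = agg_system_ci = 0.0

    # Little's law: time-average number in the ED system vs lambda * W
    l_ed = float(np.mean([r["l_ed"] for r in reps]))
    lam_w = float((lam_obs.mean(axis=0) * system.mean(axis=0)).sum())

    return SimResult(
        labels=scenario.class_labels,
        delay_mean=tuple(delay.mean(axis=0)),
        delay_ci_half=tuple(_ci_half(delay[:, k]) for k in range(K)),
        system_mean=tuple(system.mean(axis=0)),
        system_ci_half=tuple(_ci_half(system[:, k]) for k in range(K)),
        aggregate_delay=agg_delay,
        aggregate_system=agg_system,
        aggregate_delay_ci_half=agg_delay_ci,
        aggregate_system_ci_half=agg_system_ci,
        blocking_mean=float(blocking.mean()),
        blocking_ci_half=_ci_half(blocking),
        iu_attempts_total=int(sum(r["iu_attempts"] for r in reps)),
        ed_utilization=float(np.mean([r["ed_util"] for r in reps])),
        iu_utilization=float(np.mean([r["iu_util"] for r in reps])),
        preemptions_per_hour=float(np.mean([r["preempt_rate"] for r in reps])),
        little_l=(l_ed,),
        little_lambda_w=(lam_w,),
        replications=config.replications,
        horizon=config.horizon,
        warmup=config.warmup,
    )


def compare_analytic_sim(scenario: Scenario, config: SimConfig) -> pd.DataFrame:
    """Side-by-side analytic vs simulated waits and blocking, with rel. errors."""
    rep = solve(scenario)
    sim = simulate(scenario, config)
    rows = []
    for k, lab in enumerate(scenario.class_labels):
        ana_sys = rep.waits.system_time[k] if rep.waits else float("nan")
        ana_del = rep.waits.queueing_delay[k] if rep.waits else float("nan")
        rows.append({
            "row": lab,
            "analytic_system_time": ana_sys,
            "sim_system_time": sim.system_mean[k],
            "analytic_delay": ana_del,
            "sim_delay": sim.delay_mean[k],
            "rel_err_system": _rel(ana_sys, sim.system_mean[k]),
        })
    ana_agg = rep.waits.aggregate_system_time if rep.waits else float("nan")
    rows.append({
        "row": "aggregate",
        "analytic_system_time": ana_agg,
        "sim_system_time": sim.aggregate_system,
        "analytic_delay": rep.waits.aggregate_queueing_delay if rep.waits else float("nan"),
        "sim_delay": sim.aggregate_delay,
        "rel_err_system": _rel(ana_agg, sim.aggregate_system),
    })
    rows.append({
        "row": "iu_blocking",
        "analytic_system_time": rep.p_b.p_b,
        "sim_system_time": sim.blocking_mean,
        "analytic_delay": float("nan"),
        "sim_delay": float("nan"),
        "rel_err_system": _rel(rep.p_b.p_b, sim.blocking_mean),
    })
    return pd.DataFrame(rows)


def _rel(a: float, b: float) -> float:
    denom = max(abs(a), abs(b))
    return abs(a - b) / denom if denom > 0 else 0.0
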