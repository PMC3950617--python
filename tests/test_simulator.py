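"""Discrete-event simulator: determinism, exact benchmarks, invariants."""

from dataclasses import replace

import numpy as np
import pytest

from edq import (
    Scenario,
    SimConfig,
    TriangularDist,
    compare_analytic_sim,
    erlang_b,
    erlang_c,
    simulate,
)


def exp_sampler(mean):
    def f(rng, size, k=None):
        return rng.exponential(mean, size)
    return f


@pytest.fixture(scope="module")
def two_class_mm2():
    return Scenario(
        arrival_rates=(0.9, 0.9), lambda_direct=0.0, transfer_fraction=0.0,
        ed_service=TriangularDist(0.5, 1.0, 1.5), iu_los=TriangularDist(24, 96, 168),
        c1=2, c2=10,
    )


def test_same_seed_reproduces_bitwise(baseline):
    cfg = SimConfig(horizon=300.0, warmup=50.0, replications=3, seed=11)
    assert simulate(baseline, cfg) == simulate(baseline, cfg)


def test_zero_arrivals_yield_empty_statistics(baseline):
    sc = replace(baseline, arrival_rates=(0.0,) * 5, lambda_direct=0.0)
    res = simulate(sc, SimConfig(horizon=200.0, warmup=20.0, replications=2, seed=1))
    assert all(v == 0.0 for v in res.delay_mean)
    assert res.blocking_mean == 0.0 and res.ed_utilization == 0.0


def test_preemptive_mm2_against_exact_benchmarks(two_class_mm2):
    res = simulate(two_class_mm2,
                   SimConfig(horizon=2000.0, warmup=200.0, replications=40, seed=17),
                   ed_sampler=exp_sampler(1.0))
    # class 1 sees a plain M/M/2 at its own arrival rate
    wq1 = erlang_c(2, 0.9, 1.0) / (2 - 0.9)
    assert abs(res.delay_mean[0] - wq1) <= 3 * res.delay_ci_half[0]
    # identical exponential classes: aggregate sojourn equals the FCFS value
    w_sys = 1.0 + erlang_c(2, 1.8, 1.0) / (2 - 1.8)
    assert abs(res.aggregate_system - w_sys) <= 3 * res.aggregate_system_ci_half


def test_priority_ordering_of_simulated_delays(baseline):
    sc = replace(baseline, c1=5)
    res = simulate(sc, SimConfig(horizon=1500.0, warmup=150.0, replications=10, seed=3))
    d = res.delay_mean
    assert d[0] <= d[2] + 1e-9 <= d[4] + 2e-2  # acuity ordering, small noise slack


def test_iu_loss_system_matches_erlang_b(baseline):
    # direct-only admissions with exponential stays: exact M/M/c/c
    sc = replace(baseline, c2=10, lambda_direct=0.8, transfer_fraction=0.0)
    res = simulate(sc, SimConfig(horizon=2000.0, warmup=200.0, replications=30, seed=5),
                   iu_sampler=exp_sampler(10.0))
    assert abs(res.blocking_mean - erlang_b(10, 8.0)) <= 3 * res.blocking_ci_half


def test_blocking_monotone_in_iu_beds_paired_seeds(baseline):
    sc = replace(baseline, lambda_direct=0.8, transfer_fraction=0.0,
                 iu_los=TriangularDist(5.0, 10.0, 15.0))
    cfg = SimConfig(horizon=1000.0, warmup=100.0, replications=8, seed=23)
    vals = [simulate(replace(sc, c2=c2), cfg).blocking_mean for c2 in (6, 8, 10, 14)]
    assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


def test_littles_law_in_stable_run(baseline):
    res = simulate(baseline, SimConfig(horizon=2000.0, warmup=200.0,
                                       replications=10, seed=9))
    l, lam_w = res.little_l[0], res.little_lambda_w[0]
    assert l == pytest.approx(lam_w, rel=0.05)


def test_boarding_occupies_ed_beds(baseline):
    # tiny IU forces boarding; ED utilization must exceed the no-boarding level
    sc = replace(baseline, c2=3, transfer_fraction=0.3, lambda_direct=0.0)
    cfg = SimConfig(horizon=800.0, warmup=100.0, replications=5, seed=13)
    blocked = simulate(sc, cfg)
    free = simulate(replace(sc, c2=400), cfg)
    assert blocked.blocking_mean > 0.5
    assert blocked.ed_utilization > free.ed_utilization


def test_overloaded_run_reports_rather_than_crashes(baseline):
    sc = replace(baseline, c1=2)
    res = simulate(sc, SimConfig(horizon=300.0, warmup=50.0, replications=2, seed=2))
    assert res.ed_utilization > 0.95


def test_comparison_table_layout(baseline):
    cfg = SimConfig(horizon=400.0, warmup=50.0, replications=3, seed=4)
    t1 = compare_analytic_sim(baseline, cfg)
    t2 = compare_analytic_sim(baseline, cfg)
    assert t1.equals(t2)  # deterministic rerun
    assert list(t1["row"]) == ["CTAS-I", "CTAS-II", "CTAS-III", "CTAS-IV", "CTAS-V",
                               "aggregate", "iu_blocking"]
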