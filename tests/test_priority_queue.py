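"""Multi-priority M/G/c waiting-time chain against classical closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edq import (
    ClassMoments,
    InstabilityError,
    erlang_c,
    w_mg1_priority,
    w_mgc_fcfs,
    w_mgc_priority,
    wq_mg1_fcfs,
)


def erlang_c_brute(c: int, a: float, terms: int = 4000) -> float:
    """Delay probability from the defining series with a long explicit tail."""
    rho = a / c
    head = sum(a**t / math.factorial(t) for t in range(c))
    tail = sum(a**c / math.factorial(c) * rho ** (t - c) for t in range(c, c + terms))
    return (a**c / (math.factorial(c) * (1 - rho))) / (head + tail)


class TestSingleServerFcfs:
    def test_empty_system(self):
        assert wq_mg1_fcfs(0.0, 1.0, 2.0) == 0.0

    def test_exponential_reduces_to_mm1_delay(self):
        # M/M/1: Wq = rho/(1-rho) * S
        assert wq_mg1_fcfs(0.5, 1.0, 2.0) == pytest.approx(1.0)

    def test_deterministic_is_half_the_mm1_delay(self):
        assert wq_mg1_fcfs(0.5, 1.0, 1.0) == pytest.approx(0.5)

    def test_unstable_load_raises(self):
        with pytest.raises(InstabilityError):
            wq_mg1_fcfs(1.0, 1.0, 2.0)


class TestErlangC:
    def test_single_server_equals_utilisation(self):
        assert erlang_c(1, 0.3, 1.0) == pytest.approx(0.3)

    def test_two_servers_unit_offered_load(self):
        assert erlang_c(2, 1.0, 1.0) == pytest.approx(1.0 / 3.0)

    def test_zero_arrivals(self):
        assert erlang_c(4, 0.0, 1.0) == 0.0

    @pytest.mark.parametrize("c,a", [(2, 1.0), (3, 2.1), (8, 6.0), (20, 15.0)])
    def test_matches_brute_force_series(self, c, a):
        assert erlang_c(c, a, 1.0) == pytest.approx(erlang_c_brute(c, a), rel=1e-9)

    def test_unstable_load_raises(self):
        with pytest.raises(InstabilityError):
            erlang_c(2, 2.0, 1.0)


class TestMultiServerFcfs:
    def test_mm2_sojourn_exact(self):
        assert w_mgc_fcfs(2, 1.0, 1.0, 2.0) == pytest.approx(4.0 / 3.0)

    def test_mm1_sojourn_exact(self):
        assert w_mgc_fcfs(1, 0.5, 1.0, 2.0) == pytest.approx(2.0)

    def test_empty_system_exponential(self):
        assert w_mgc_fcfs(3, 0.0, 1.0, 2.0) == pytest.approx(1.0)


class TestSingleServerPriority:
    def test_one_class_reduces_to_mm1_sojourn(self):
        cm = ClassMoments(lam=(0.5,), s_mean=(1.0,), s_m2=(2.0,))
        assert w_mg1_priority(cm)[0] == pytest.approx(2.0)

    def test_two_identical_exponential_classes(self):
        cm = ClassMoments(lam=(0.25, 0.25), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        w = w_mg1_priority(cm)
        assert w[0] == pytest.approx(4.0 / 3.0)
        assert w[1] == pytest.approx(8.0 / 3.0)

    def test_work_conservation_identity(self):
        # lambda-weighted mean across identical exponential classes equals
        # the aggregate M/M/1 sojourn, exactly
        cm = ClassMoments(lam=(0.1, 0.2, 0.2), s_mean=(1.0,) * 3, s_m2=(2.0,) * 3)
        w = w_mg1_priority(cm)
        agg = sum(l * x for l, x in zip(cm.lam, w)) / 0.5
        assert abs(agg - 2.0) < 1e-10

    def test_instability_names_first_unstable_class(self):
        cm = ClassMoments(lam=(0.5, 0.6), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        with pytest.raises(InstabilityError, match="class 2"):
            w_mg1_priority(cm)


class TestMultiServerPriority:
    def test_single_server_case_uses_exact_priority_formula(self):
        cm = ClassMoments(lam=(0.2, 0.2), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        est = w_mgc_priority(1, cm)
        assert est.system_time == pytest.approx(w_mg1_priority(cm))

    def test_single_class_case_uses_fcfs_estimate(self):
        cm = ClassMoments(lam=(1.0,), s_mean=(1.0,), s_m2=(2.0,))
        est = w_mgc_priority(2, cm)
        assert est.system_time[0] == pytest.approx(w_mgc_fcfs(2, 1.0, 1.0, 2.0))

    def test_two_class_mm2_composition(self):
        cm = ClassMoments(lam=(0.5, 0.5), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        est = w_mgc_priority(2, cm)
        assert est.system_time[0] == pytest.approx(16.0 / 9.0, rel=1e-9)
        assert est.system_time[1] == pytest.approx(32.0 / 9.0, rel=1e-9)
        # delays subtract the class service mean, floored at zero
        assert est.queueing_delay[0] == pytest.approx(16.0 / 9.0 - 1.0)

    def test_priority_ordering(self):
        cm = ClassMoments(lam=(0.3, 0.3, 0.3), s_mean=(0.8,) * 3, s_m2=(1.3,) * 3)
        est = w_mgc_priority(2, cm)
        assert est.system_time[0] <= est.system_time[1] <= est.system_time[2]

    def test_building_blocks_monotone_in_arrival_rate(self):
        # the exact single-server pieces are monotone in every class rate
        # (the heuristic c-server composition is not, since its reference
        # M/G/1 delay sits in the denominator)
        def mg1(lam3):
            cm = ClassMoments(lam=(0.3, 0.3, lam3), s_mean=(0.8,) * 3, s_m2=(1.3,) * 3)
            return w_mg1_priority(cm)

        lo, hi = mg1(0.2), mg1(0.5)
        assert all(h >= l - 1e-12 for l, h in zip(lo, hi))
        assert erlang_c(3, 1.2, 0.8) >= erlang_c(3, 0.9, 0.8)
        assert wq_mg1_fcfs(0.6, 0.8, 1.3) >= wq_mg1_fcfs(0.4, 0.8, 1.3)

    def test_aggregate_is_rate_weighted_average(self):
        cm = ClassMoments(lam=(0.4, 0.6), s_mean=(0.7, 0.9), s_m2=(1.0, 1.6))
        est = w_mgc_priority(3, cm)
        agg = sum(l * w for l, w in zip(cm.lam, est.system_time)) / 1.0
        assert est.aggregate_system_time == pytest.approx(agg)

    def test_unscaled_variant_requires_stable_reference_queue(self):
        cm = ClassMoments(lam=(1.0, 1.0), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        w_mgc_priority(3, cm, scaling="scaled")  # fine
        with pytest.raises(InstabilityError):
            w_mgc_priority(3, cm, scaling="unscaled")

    def test_empty_system(self):
        cm = ClassMoments(lam=(0.0, 0.0), s_mean=(1.0, 1.0), s_m2=(2.0, 2.0))
        est = w_mgc_priority(2, cm)
        assert est.system_time == (1.0, 1.0)
        assert est.queueing_delay == (0.0, 0.0)


@given(
    st.integers(1, 5),
    st.lists(st.floats(0.01, 0.4), min_size=2, max_size=5),
    st.floats(0.3, 1.2),
)
@settings(max_examples=60, deadline=None)
def test_composition_outputs_nonnegative_and_ordered(c, lams, s_mean):
    s_m2 = 1.7 * s_mean * s_mean  # mildly variable service law
    cm = ClassMoments(lam=tuple(lams), s_mean=(s_mean,) * len(lams), s_m2=(s_m2,) * len(lams))
    if cm.lam_total * s_mean >= c:
        return
    est = w_mgc_priority(c, cm)
    assert all(w >= 0 for w in est.system_time)
    assert all(b >= a - 1e-9 for a, b in zip(est.system_time, est.system_time[1:]))
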