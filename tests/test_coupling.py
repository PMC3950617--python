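"""ED-IU fixed point: modified moments, bounds, root search, full solve."""

from dataclasses import replace

import numpy as np
import pytest

from edq import (
    Scenario,
    TriangularDist,
    find_mu_roots,
    fixed_point_residual,
    make_fixture,
    modified_moments,
    mu_bounds,
    solve,
)


class TestModifiedMoments:
    def test_no_blocking_leaves_moments_unchanged(self):
        assert modified_moments(0.5, 0.4, 0.0, 48.0) == (0.5, 0.4)

    def test_full_blocking_shift(self):
        mean, m2 = modified_moments(0.5333, 0.3183, 1.0, 48.0)
        assert mean == pytest.approx(48.5333)
        assert m2 == pytest.approx(0.3183 + 2 * 0.5333 * 48 + 48**2)

    def test_jensen_preserved(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = rng.uniform(0.1, 2)
            m2 = m * m * rng.uniform(1.0, 3.0)
            pb = rng.uniform(0, 1)
            bm = rng.uniform(0, 100)
            mm, mm2 = modified_moments(m, m2, pb, bm)
            assert mm2 >= mm * mm - 1e-9
            assert mm >= m


class TestMuBounds:
    def test_baseline_bracket(self, baseline):
        mu_min, mu_max = mu_bounds(baseline)
        assert mu_max == pytest.approx(1.875)
        # boarding mean for 125 beds with 1-7 day stays sits a few hours
        # above the 24 h lower support limit
        assert 1 / mu_min - 1 / mu_max == pytest.approx(baseline.boarding_mean())
        assert 0.02 < mu_min < 0.05

    def test_degenerate_stay_collapses_bracket(self, baseline):
        sc = replace(baseline, iu_los=TriangularDist(0.0, 0.0, 0.0))
        mu_min, mu_max = mu_bounds(sc)
        assert mu_min == pytest.approx(mu_max)

    def test_ordering_always_holds(self):
        for seed in range(20):
            sc = make_fixture(seed, "moderate")
            mu_min, mu_max = mu_bounds(sc)
            assert mu_min <= mu_max


class TestResidualAndRoots:
    def test_uncoupled_limit_root_at_mu1(self, baseline):
        # enormous IU -> no blocking anywhere -> unique root at mu_1
        sc = replace(baseline, c2=500)
        assert abs(fixed_point_residual(sc.mu1, sc)) < 1e-12
        fp = find_mu_roots(sc)
        assert fp.status == "ok"
        assert fp.roots[-1] == pytest.approx(sc.mu1, abs=1e-9)

    def test_baseline_roots_and_feasibility(self, baseline):
        fp = find_mu_roots(baseline)
        assert fp.status == "ok"
        assert all(abs(r) < 1e-10 for r in fp.residuals)
        assert fp.mu_min <= fp.mu_hat_min <= fp.mu_hat_max <= fp.mu_max
        assert fp.sufficient_met and fp.necessary_met

    def test_sufficient_implies_necessary(self):
        for seed in range(25):
            for regime in ("light", "moderate", "congested"):
                fp = find_mu_roots(make_fixture(seed, regime))
                if fp.status == "ok" and fp.sufficient_met:
                    assert fp.necessary_met

    def test_residual_positive_at_lower_bound(self, baseline):
        mu_min, _ = mu_bounds(baseline)
        assert fixed_point_residual(mu_min, baseline) >= -1e-12


class TestSolve:
    def test_baseline_converges_and_matches_root_search(self, baseline):
        rep = solve(baseline)
        assert rep.status == "ok"
        assert rep.converged
        assert min(abs(rep.mu_hat - r) for r in rep.fixed_point.roots) < 1e-6

    def test_forced_no_blocking_matches_uncoupled_model(self, baseline):
        from edq import w_mgc_priority

        sc = replace(baseline, c2=500)
        rep = solve(sc)
        raw = sc.raw_moments()
        uncoupled = w_mgc_priority(sc.c1, raw, scaling=sc.bondi_scaling)
        assert rep.waits.system_time == pytest.approx(uncoupled.system_time, rel=1e-9)

    def test_overload_reported_unstable(self, baseline):
        sc = replace(baseline, c1=5,
                     arrival_rates=tuple(10 * l for l in baseline.arrival_rates))
        assert solve(sc).status == "unstable"

    def test_modified_means_dominate_raw_means(self):
        for seed in range(10):
            sc = make_fixture(seed, "congested")
            rep = solve(sc)
            raw = sc.raw_moments()
            assert 0.0 <= rep.p_b.p_b <= 1.0
            for m_mod, m_raw in zip(rep.modified_moments.s_mean, raw.s_mean):
                assert m_mod >= m_raw - 1e-12

    def test_coupling_relaxes_monotonically_in_iu_beds(self, baseline):
        # more IU beds -> less blocking -> faster effective ED service
        sc = replace(baseline, c1=8, transfer_fraction=0.1)
        pbs, mus = [], []
        for c2 in (99, 101, 104, 110, 125):
            rep = solve(replace(sc, c2=c2))
            pbs.append(rep.p_b.p_b)
            mus.append(rep.mu_hat)
        assert all(b <= a + 1e-12 for a, b in zip(pbs, pbs[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(mus, mus[1:]))

    def test_zero_arrivals_rejected(self, baseline):
        with pytest.raises(ValueError):
            solve(replace(baseline, arrival_rates=(0.0,) * 5))
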