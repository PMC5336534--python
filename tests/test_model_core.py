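import numpy as np
import pytest

from hpmcerode.model_core import (ParamTimeline, StructuralParams,
                                  TimelineError, analytic_segment_solution,
                                  mechanism_rate, michaelis_menten_rate,
                                  numeric_segment_solution,
                                  solve_release_profile)


class TestRates:
    def test_michaelis_menten_half_maximal_at_km(self):
        assert michaelis_menten_rate(34.2, 22.0, 34.2) == pytest.approx(11.0)

    def test_michaelis_menten_depleted_and_saturated(self):
        assert michaelis_menten_rate(0.0, 22.0, 34.2) == 0.0
        assert michaelis_menten_rate(1e6 * 34.2, 22.0, 34.2) == \
            pytest.approx(22.0, rel=1e-5)

    def test_michaelis_menten_rejects_negative(self):
        with pytest.raises(ValueError):
            michaelis_menten_rate(-1.0, 22.0, 34.2)

    def test_mechanism_rate_special_cases(self):
        # gamma = 1 collapses to first-order decline R * H
        assert mechanism_rate(50.0, 0.2, 1.0, 140.0, 350.0) == \
            pytest.approx(0.2 * 50.0)
        assert mechanism_rate(0.0, 0.2, 0.8, 140.0, 350.0) == 0.0
        # gamma = 0 is zero-order: R * dose / weight
        assert mechanism_rate(50.0, 0.2, 0.0, 140.0, 350.0) == \
            pytest.approx(0.2 * 140.0 / 350.0)
        with pytest.raises(ValueError):
            mechanism_rate(50.0, 0.2, -0.5, 140.0, 350.0)


class TestSegmentSolution:
    def test_identity_at_zero_duration(self):
        assert analytic_segment_solution(140.0, 22.0, 34.2, 0.0) == 140.0

    def test_zero_order_limit_as_km_vanishes(self):
        # km -> 0 gives linear depletion h0 - vmax * dt
        assert analytic_segment_solution(140.0, 22.0, 1e-6, 2.0) == \
            pytest.approx(140.0 - 44.0, abs=1e-3)
        assert analytic_segment_solution(10.0, 22.0, 1e-6, 2.0) == \
            pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("h0,vmax,km,dt", [
        (140.0, 22.0, 34.2, 2.0),
        (140.0, 9.9, 34.2, 8.0),
        (70.0, 25.0, 50.0, 1.5),
        (140.0, 22.0, 5.0, 6.0),
    ])
    def test_lambert_w_matches_adaptive_integration(self, h0, vmax, km, dt):
        a = analytic_segment_solution(h0, vmax, km, dt)
        n = numeric_segment_solution(h0, vmax, km, dt)
        assert a == pytest.approx(n, abs=1e-8, rel=1e-8)

    def test_overflow_regime_is_finite_and_accurate(self):
        # tiny km drives the exponent far beyond floating-point range
        a = analytic_segment_solution(140.0, 22.0, 1e-4, 3.0)
        assert np.isfinite(a)
        assert a == pytest.approx(140.0 - 66.0, abs=1e-2)


class TestReleaseProfile:
    params = StructuralParams(vmax=22.0, km=34.2, tlag=0.5)
    tl = ParamTimeline.constant(22.0, 34.2)

    def test_no_release_before_lag(self):
        states = solve_release_profile(self.params, self.tl, 140.0,
                                       [0.0, 0.2, 0.5])
        assert all(s.released == 0.0 for s in states)

    def test_full_depletion_at_long_times(self):
        (s,) = solve_release_profile(self.params, self.tl, 140.0, [500.0])
        assert s.released == pytest.approx(140.0, abs=1e-6)

    def test_conservation_and_monotonicity(self):
        t = np.linspace(0, 14, 57)
        states = solve_release_profile(self.params, self.tl, 140.0, t)
        rel = np.array([s.released for s in states])
        rem = np.array([s.hpmc_tablet for s in states])
        assert np.allclose(rel + rem, 140.0, rtol=1e-9)
        assert np.all(np.diff(rel) >= -1e-12)

    def test_doubling_vmax_never_decreases_release(self):
        t = np.linspace(0, 14, 29)
        lo = solve_release_profile(self.params, self.tl, 140.0, t)
        hi = solve_release_profile(
            StructuralParams(vmax=44.0, km=34.2, tlag=0.5),
            ParamTimeline.constant(44.0, 34.2), 140.0, t)
        assert all(b.released >= a.released - 1e-12
                   for a, b in zip(lo, hi))

    def test_timeline_splitting_invariance(self):
        t = np.linspace(0, 14, 29)
        split = ParamTimeline([0.0, 3.0, 7.0],
                              [(22.0, 34.2)] * 3)
        a = solve_release_profile(self.params, self.tl, 140.0, t)
        b = solve_release_profile(self.params, split, 140.0, t)
        assert np.allclose([s.released for s in a],
                           [s.released for s in b], atol=1e-10)

    def test_analytic_and_numeric_chained_solutions_agree(self):
        t = np.linspace(0, 14, 29)
        tl = ParamTimeline([0.0, 1.5, 4.0], [(22.0, 34.2), (30.0, 18.0),
                                             (8.0, 40.0)])
        a = solve_release_profile(self.params, tl, 140.0, t, "analytic")
        n = solve_release_profile(self.params, tl, 140.0, t, "numeric")
        diff = max(abs(x.released - y.released) for x, y in zip(a, n))
        assert diff < 1e-6 * 140.0

    def test_mechanism_gamma_one_is_exponential_decline(self):
        p = StructuralParams(vmax=22.0, km=34.2, tlag=0.3, r_basal=0.25,
                             gamma=1.0)
        t = np.array([0.5, 1.0, 3.0, 8.0])
        states = solve_release_profile(p, self.tl, 140.0, t,
                                       model="mechanism")
        expected = 140.0 * np.exp(-0.25 * (t - 0.3))
        assert np.allclose([s.hpmc_tablet for s in states], expected,
                           rtol=1e-8)

    def test_invalid_timeline_rejected(self):
        with pytest.raises(TimelineError):
            ParamTimeline([1.0], [(22.0, 34.2)])
        with pytest.raises(TimelineError):
            ParamTimeline([0.0, 0.0], [(22.0, 34.2), (22.0, 34.2)])
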