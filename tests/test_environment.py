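import numpy as np
import pytest

from hpmcerode.covariates import CovariateParams
from hpmcerode.environment import (COLON, DISTAL_SI, PROXIMAL_SI, STOMACH,
                                   GILocationRecord, PhPrior, RpmParams,
                                   build_environment_timeline,
                                   draw_segment_ph, segment_small_intestine,
                                   timeline_from_environment)
from hpmcerode.formulations import FORMULATIONS


def rec(si=0.8, colon=4.0, prandial="fasting"):
    return GILocationRecord(subject=1, occasion=1, prandial=prandial,
                            si_entry=si, colon_entry=colon)


class TestSegmentation:
    def test_fixed_offset_rule(self):
        seg = segment_small_intestine(rec(), "fixed_offset_1h")
        assert seg.segments == (STOMACH, PROXIMAL_SI, DISTAL_SI, COLON)
        assert seg.entry_times == (0.0, 0.8, 1.8, 4.0)

    def test_fractional_sitt_rule(self):
        seg = segment_small_intestine(rec(), "fractional_sitt")
        # transfer at SI entry + 45% of the 3.2 h transit
        assert seg.entry_times[2] == pytest.approx(0.8 + 0.45 * 3.2)

    def test_short_transit_gives_no_distal_interval(self):
        seg = segment_small_intestine(rec(colon=1.3), "fixed_offset_1h")
        assert DISTAL_SI not in seg.segments
        assert seg.segments == (STOMACH, PROXIMAL_SI, COLON)

    def test_rules_agree_when_offset_matches_fraction(self):
        # 0.45 * SITT = 1 h  <=>  SITT = 1/0.45
        r = rec(colon=0.8 + 1.0 / 0.45)
        a = segment_small_intestine(r, "fixed_offset_1h")
        b = segment_small_intestine(r, "fractional_sitt")
        assert np.allclose(a.entry_times, b.entry_times)

    def test_open_ended_record_without_colon_entry(self):
        seg = segment_small_intestine(rec(colon=None), "fixed_offset_1h")
        assert seg.segments == (STOMACH, PROXIMAL_SI, DISTAL_SI)

    def test_estimated_offset_uses_supplied_value(self):
        seg = segment_small_intestine(rec(), "estimated_offset", offset=0.5)
        assert seg.entry_times[2] == pytest.approx(1.3)


class TestPhPriors:
    prior = PhPrior()

    @pytest.mark.parametrize("segment, prandial, mean", [
        (STOMACH, "fasting", 1.73),
        (STOMACH, "postprandial", 4.90),
        (PROXIMAL_SI, "fasting", 6.63),
        (DISTAL_SI, "fasting", 7.49),
        (COLON, "postprandial", 6.63),
    ])
    def test_deterministic_mode_returns_prior_mean(self, segment,
                                                   prandial, mean):
        assert draw_segment_ph(segment, prandial, self.prior) == mean

    def test_seeded_draws_reproducible_and_bounded(self):
        d1 = [draw_segment_ph(STOMACH, "fasting", self.prior,
                              np.random.default_rng(5)) for _ in range(3)]
        d2 = [draw_segment_ph(STOMACH, "fasting", self.prior,
                              np.random.default_rng(5)) for _ in range(3)]
        assert d1 == d2
        rng = np.random.default_rng(0)
        draws = [draw_segment_ph(STOMACH, "fasting", self.prior, rng)
                 for _ in range(200)]
        assert min(draws) >= 0.5 and max(draws) <= 9.0

    def test_unknown_segment_rejected(self):
        with pytest.raises(ValueError):
            self.prior.lookup("duodenum", "fasting")


class TestEnvironmentTimeline:
    def test_prandial_status_switches_only_stomach_ph(self):
        seg = segment_small_intestine(rec(), "fixed_offset_1h")
        fast = build_environment_timeline(seg, "fasting")
        fed = build_environment_timeline(seg, "postprandial")
        assert fast[0][1] == 1.73 and fed[0][1] == 4.90
        assert [e[1] for e in fast[1:]] == [e[1] for e in fed[1:]]

    def test_segment_rpm_assignment(self):
        seg = segment_small_intestine(rec(), "fixed_offset_1h")
        env = build_environment_timeline(seg, "fasting", rpm=RpmParams())
        assert [e[2] for e in env] == [39.5, 93.3, 31.1, 9.99]

    def test_timeline_feeds_covariate_model(self):
        seg = segment_small_intestine(rec(), "fixed_offset_1h")
        env = build_environment_timeline(seg, "fasting")
        tl = timeline_from_environment(env, CovariateParams(),
                                       FORMULATIONS["F3"])
        assert list(tl.breakpoints) == [0.0, 0.8, 1.8, 4.0]
        # gastric pH 1.73 lowers Km strongly relative to intestine
        assert tl.segment_params[0][1] < tl.segment_params[1][1]

    def test_recorded_ph_values_override_draws(self):
        seg = segment_small_intestine(rec(), "fixed_offset_1h")
        env = build_environment_timeline(seg, "fasting",
                                         ph_values=[2.0, 6.0, 7.0, 6.5])
        assert [e[1] for e in env] == [2.0, 6.0, 7.0, 6.5]
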