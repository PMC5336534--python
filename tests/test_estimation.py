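import numpy as np
import pytest
from scipy.integrate import quad

from hpmcerode.estimation import (ErrorModel, Param, ParamSet,
                                  conditional_minus2ll, cv_percent_to_omega,
                                  fit_population, foce_minus2ll,
                                  laplace_nested_m2ll, laplace_scalar_m2ll,
                                  omega_to_cv_percent)
from hpmcerode.model_core import _lambertw_of_exp

TIMES = np.array([0.5, 1.0, 2.0, 4.0, 6.0])


def mm_pred(eta, vmax=22.0, km=34.2, dose=140.0, times=TIMES):
    """Michaelis-Menten released amounts with a log-normal rate effect."""
    v = vmax * np.exp(eta)
    log_x = np.log(dose / km) + (dose - v * times) / km
    return dose - km * _lambertw_of_exp(log_x)


class TestErrorModel:
    def test_combined_with_zero_prop_equals_additive(self):
        dv = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.5, 1.5, 2.5])
        add = ErrorModel("additive", sigma_add=2.0)
        comb = ErrorModel("combined", sigma_add=2.0, sigma_prop=0.0)
        assert conditional_minus2ll(dv, pred, add) == \
            conditional_minus2ll(dv, pred, comb)

    def test_zero_residuals_unit_sigma_closed_form(self):
        pred = np.array([5.0, 6.0, 7.0, 8.0])
        err = ErrorModel("additive", sigma_add=1.0)
        assert conditional_minus2ll(pred, pred, err) == \
            pytest.approx(4 * np.log(2 * np.pi))

    def test_doubling_sigma_changes_value_by_closed_form(self):
        dv = np.array([1.0, 3.0])
        pred = np.array([2.0, 2.0])
        v1 = conditional_minus2ll(dv, pred, ErrorModel("additive", 1.0))
        v2 = conditional_minus2ll(dv, pred, ErrorModel("additive", 2.0))
        # n*log(4) from the variance term, RSS scaled by 1/4
        assert v2 - v1 == pytest.approx(2 * np.log(4.0) - 2.0 * (1 - 0.25))

    def test_all_zero_sigmas_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel("additive", sigma_add=0.0)

    def test_nonfinite_prediction_flags_not_crashes(self):
        err = ErrorModel("additive", 1.0)
        val = conditional_minus2ll(np.ones(2), np.array([np.nan, 1.0]), err)
        assert val == np.inf


class TestLaplace:
    err = ErrorModel("additive", sigma_add=2.0)

    def test_zero_variance_reduces_to_conditional_at_mode_zero(self):
        dv = mm_pred(0.1)
        m2, eta = laplace_scalar_m2ll(mm_pred, dv, 0.0, self.err)
        assert eta == 0.0
        assert m2 == conditional_minus2ll(dv, mm_pred(0.0), self.err)
        # the dataset-level objective sums per-unit terms
        ofv = foce_minus2ll([mm_pred, mm_pred], [dv, dv], 0.0, self.err)
        assert ofv == pytest.approx(2.0 * m2)

    def test_linear_model_marginal_is_exact(self):
        # linear-in-eta predictions: Laplace equals the Gaussian closed form
        base, slope = np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 0.5])
        dv = np.array([1.5, 2.2, 3.6])
        om2, s2 = 0.25, 4.0

        def lin(e):
            return base + slope * e

        m2, _ = laplace_scalar_m2ll(lin, dv, om2, self.err)
        cov = s2 * np.eye(3) + om2 * np.outer(slope, slope)
        res = dv - base
        exact = (np.log(np.linalg.det(2 * np.pi * cov))
                 + res @ np.linalg.solve(cov, res))
        assert m2 == pytest.approx(exact, abs=1e-5)

    def test_scalar_laplace_matches_quadrature(self):
        rng = np.random.default_rng(0)
        dv = mm_pred(0.15) + rng.normal(0, 2, TIMES.size)
        om2 = 0.09
        m2, _ = laplace_scalar_m2ll(mm_pred, dv, om2, self.err)

        def joint(e):
            p = mm_pred(e)
            var = self.err.variance(p)
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (dv - p) ** 2 / var)
            return np.exp(ll - 0.5 * (e * e / om2 + np.log(2 * np.pi * om2)))

        integral, _ = quad(joint, -3, 3, limit=200)
        assert m2 == pytest.approx(-2 * np.log(integral), abs=0.1)

    def test_nested_laplace_matches_quadrature(self):
        # one subject, two occasions: 3-dimensional random-effect vector
        rng = np.random.default_rng(1)
        om2_bsv, om2_bov = 0.04, 0.02
        dvs = [mm_pred(0.1) + rng.normal(0, 2, TIMES.size),
               mm_pred(-0.05) + rng.normal(0, 2, TIMES.size)]
        m2, _ = laplace_nested_m2ll([mm_pred, mm_pred], dvs, om2_bsv,
                                    om2_bov, self.err)

        from scipy.integrate import tplquad

        def joint(o2, o1, s):
            tot = 0.0
            for dvj, oj in zip(dvs, (o1, o2)):
                p = mm_pred(s + oj)
                var = self.err.variance(p)
                tot -= 0.5 * np.sum(np.log(2 * np.pi * var)
                                    + (dvj - p) ** 2 / var)
            tot -= 0.5 * (s * s / om2_bsv + np.log(2 * np.pi * om2_bsv))
            tot -= 0.5 * (o1 * o1 / om2_bov + o2 * o2 / om2_bov
                          + 2 * np.log(2 * np.pi * om2_bov))
            return np.exp(tot)

        integral, _ = tplquad(joint, -1.2, 1.2, -0.8, 0.8, -0.8, 0.8,
                              epsabs=1e-12)
        assert m2 == pytest.approx(-2 * np.log(integral), abs=0.1)

    def test_nested_degenerate_variances_collapse(self):
        dvs = [mm_pred(0.0), mm_pred(0.0)]
        m2, etas = laplace_nested_m2ll([mm_pred, mm_pred], dvs, 0.0, 0.0,
                                       self.err)
        direct = sum(conditional_minus2ll(d, mm_pred(0.0), self.err)
                     for d in dvs)
        assert m2 == pytest.approx(direct)
        assert np.all(etas == 0.0)


class TestParamSet:
    def test_pack_unpack_roundtrip(self):
        ps = ParamSet([Param("a", 2.0, "log"),
                       Param("b", 0.05, "identity", scale=0.01),
                       Param("c", 7.0, "log", fixed=True)])
        x = ps.pack()
        assert x.size == 2
        vals = ps.unpack(x)
        assert vals["a"] == pytest.approx(2.0)
        assert vals["b"] == pytest.approx(0.05)
        assert vals["c"] == 7.0

    def test_log_transform_requires_positive(self):
        with pytest.raises(ValueError):
            ParamSet([Param("a", -1.0, "log")]).pack()

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ParamSet([Param("a", 1.0), Param("a", 2.0)])


class TestFitPopulation:
    def test_quadratic_objective_recovers_minimum_and_aic(self):
        # two "units" with quadratic losses; minimum at (1, 2)
        ps = ParamSet([Param("u", 0.5, "log"), Param("v", 1.0, "log")])

        def terms(x):
            vals = ps.unpack(x)
            return np.array([(vals["u"] - 1.0) ** 2,
                             (vals["v"] - 2.0) ** 2])

        res = fit_population(terms, ps, n_obs=2, compute_se=False)
        assert res.params["u"] == pytest.approx(1.0, abs=1e-4)
        assert res.params["v"] == pytest.approx(2.0, abs=1e-4)
        assert res.aic == pytest.approx(res.ofv + 4.0)

    def test_fully_fixed_model_evaluates_without_optimizing(self):
        ps = ParamSet([Param("u", 3.0, "log", fixed=True)])
        res = fit_population(lambda x: np.array([1.5]), ps, n_obs=1)
        assert res.ofv == 1.5 and res.n_free == 0 and res.se == {}


def test_cv_omega_conversion_roundtrip():
    for cv in (5.96, 14.9, 15.5):
        assert omega_to_cv_percent(cv_percent_to_omega(cv)) == \
            pytest.approx(cv)
    # small-variance convention: CV% ~ 100 * omega
    assert omega_to_cv_percent(0.01) == pytest.approx(1.0, rel=1e-3)
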