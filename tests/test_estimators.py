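import numpy as np
import pandas as pd
import pytest

import hpmcerode as h
from hpmcerode.estimation import laplace_nested_m2ll
from hpmcerode.estimators import Relation


class TestInVitroModel:
    def test_typical_prediction_at_reference_condition(self):
        X = pd.DataFrame({
            "unit_id": ["u1"] * 3, "time_h": [1.0, 2.0, 5.0],
            "formulation": ["F3"] * 3, "ph": [6.8] * 3, "rpm": [50.0] * 3,
            "ionic_mosm": [98.0] * 3})
        m = h.InVitroErosionModel()
        pred = m.predict(X, params=dict(h.INVITRO_DEFAULTS))
        # reference condition: plain Michaelis-Menten profile at tv values
        sp = h.StructuralParams(vmax=22.0, km=34.2, tlag=0.179)
        tl = h.ParamTimeline.constant(22.0, 34.2)
        states = h.solve_release_profile(sp, tl, 140.0, [1.0, 2.0, 5.0])
        assert np.allclose(pred, [s.released for s in states], atol=1e-9)

    def test_simulation_is_seed_reproducible(self, small_invitro):
        X, _ = small_invitro
        m = h.InVitroErosionModel()
        p = dict(h.INVITRO_DEFAULTS)
        a = m.simulate(X, np.random.default_rng(3), params=p)
        b = m.simulate(X, np.random.default_rng(3), params=p)
        assert np.array_equal(a, b)

    def test_fit_recovers_structure_and_masks(self, small_invitro):
        X, y = small_invitro
        m = h.InVitroErosionModel(
            relations=(Relation("ph", "vmax", "linear"),
                       Relation("dcp", "km", "linear")),
            fixed={"tlag": 0.179}, compute_se=True, maxiter=150)
        m.fit(X, y)
        # masked parameter passes through untouched and gets no SE
        assert m.params_["tlag"] == 0.179
        assert "tlag" not in m.se_
        assert m.result_.aic == pytest.approx(
            m.ofv_ + 2 * m.result_.n_free)
        assert m.se_ and all(v > 0 for v in m.se_.values())

    def test_batched_objective_matches_scalar_path(self, small_invitro):
        X, y = small_invitro
        m = h.InVitroErosionModel(compute_se=False, maxiter=40)
        m.fit(X, y)
        # independent per-unit Laplace path reproduces the fitted OFV
        assert m.minus2ll(X, y) == pytest.approx(m.ofv_, abs=1e-4)

    def test_mechanism_structural_model_fits(self, small_invitro):
        X, y = small_invitro
        m = h.InVitroErosionModel(structural="mechanism",
                                  compute_se=False, maxiter=60)
        m.fit(X, y)
        assert np.isfinite(m.ofv_)
        assert m.params_["r_basal"] > 0 and m.params_["gamma"] > 0


class TestInVivoModel:
    def test_batched_objective_matches_generic_nested(self, small_invivo):
        X, y, gi = small_invivo
        m = h.InVivoErosionModel(compute_se=False)
        Xr = X.reset_index(drop=True)
        dv = np.asarray(y, float)
        theta = m._theta()
        m._theta_cache = theta
        subjects, _ = m._occasion_data(Xr, dv, gi)
        ps = m._build_paramset()
        BO = m._batched_occasions(subjects)
        state = {"s": np.zeros(BO["n_subj"]), "o": np.zeros(BO["n_occ"])}
        params = ps.unpack(ps.pack())
        err = m._error_model(params)
        batched = m._nested_laplace_batched(
            params, BO, params["om_bsv"] ** 2, params["om_bov"] ** 2,
            err, state)
        generic = []
        for s in subjects:
            fns = [lambda e, _o=occ: m._occ_released(params, _o, theta, e)
                   for occ in s["occasions"]]
            dvs = [occ["dv"] for occ in s["occasions"]]
            m2, _ = laplace_nested_m2ll(fns, dvs, params["om_bsv"] ** 2,
                                        params["om_bov"] ** 2, err)
            generic.append(m2)
        assert np.allclose(batched, generic, atol=1e-6)

    def test_exclusion_of_f4_fasting_occasions(self, small_invivo):
        X, y, gi = small_invivo
        m = h.InVivoErosionModel(compute_se=False)
        subjects, excluded = m._occasion_data(
            X.reset_index(drop=True), np.asarray(y, float), gi)
        assert all(occ["formulation"].name == "F4"
                   and occ["prandial"] == "fasting" for occ in excluded)
        kept = [(occ["formulation"].name, occ["prandial"])
                for s in subjects for occ in s["occasions"]]
        assert ("F4", "fasting") not in kept
        assert ("F4", "postprandial") in kept

    def test_missing_gi_record_drops_occasion_with_warning(self,
                                                           small_invivo):
        X, y, gi = small_invivo
        gi_partial = gi[~((gi["subject"] == 1) & (gi["occasion"] == 1))]
        m = h.InVivoErosionModel(compute_se=False)
        with pytest.warns(RuntimeWarning, match="occasion dropped"):
            subjects, _ = m._occasion_data(
                X.reset_index(drop=True), np.asarray(y, float), gi_partial)
        occs = [(o["subject"], o["occasion"]) for s in subjects
                for o in s["occasions"]]
        assert (1, 1) not in occs

    def test_typical_prediction_uses_prior_mean_ph(self, small_invivo):
        X, y, gi = small_invivo
        m = h.InVivoErosionModel()
        p = dict(h.INVIVO_DEFAULTS)
        det = m.predict(X, gi, params=p, ph_mode="deterministic")
        rec = m.predict(X, gi, params=p, ph_mode="recorded")
        assert np.all(np.isfinite(det))
        # recorded pH draws differ from the prior means, so profiles do
        assert not np.allclose(det, rec)

    def test_simulation_reproducible_and_bounded(self, small_invivo):
        X, y, gi = small_invivo
        m = h.InVivoErosionModel()
        p = dict(h.INVIVO_DEFAULTS)
        a = m.simulate(X, gi, np.random.default_rng(1), params=p,
                       include_residual=False)
        b = m.simulate(X, gi, np.random.default_rng(1), params=p,
                       include_residual=False)
        assert np.array_equal(a, b)
        doses = X["formulation"].map(
            lambda f: h.FORMULATIONS[f].hpmc_dose).to_numpy()
        assert np.all(a <= doses + 1e-9) and np.all(a >= -1e-9)


class TestScm:
    def test_forward_selects_strong_rpm_effect_first(self):
        # data generated with an rpm effect only
        design = h.generate_invitro_design()
        cells = design[(design["formulation"] == "F3")
                       & (design["replicate"] == 1)]
        X, y = h.simulate_invitro_dataset(
            design=pd.concat([cells] * 3, ignore_index=True),
            params={"s_ph_vmax": 0.0, "s_dcp_vmax": 0.0, "s_ph_km": 0.0,
                    "s_dcp_km": 0.0, "mk4m50_vmax": 1e6},
            seed=2, times=np.arange(1.0, 10.1, 1.0))
        sel = h.StepwiseCovariateSelector(
            candidates=(Relation("rpm", "vmax", "linear"),
                        Relation("ph", "vmax", "linear"),
                        Relation("ionic", "vmax", "linear")),
            try_upgrades=False, max_steps=1, maxiter=80)
        sel.fit(X, y)
        assert sel.path_[0].relation == Relation("rpm", "vmax", "linear")
        assert sel.path_[0].delta_ofv > 3.84

    def test_path_is_deterministic_for_fixed_data(self):
        design = h.generate_invitro_design()
        cells = design[(design["formulation"] == "F3")
                       & (design["replicate"] == 1)]
        X, y = h.simulate_invitro_dataset(design=cells, seed=4,
                                          times=np.arange(1.0, 10.1, 1.0))
        kw = dict(candidates=(Relation("rpm", "vmax", "linear"),
                              Relation("ph", "vmax", "linear")),
                  try_upgrades=False, max_steps=2, maxiter=60)
        a = h.StepwiseCovariateSelector(**kw).fit(X, y)
        b = h.StepwiseCovariateSelector(**kw).fit(X, y)
        assert [s.relation for s in a.path_] == [s.relation
                                                 for s in b.path_]

    def test_thresholds_follow_alpha_levels(self):
        sel = h.StepwiseCovariateSelector()
        from scipy.stats import chi2
        assert chi2.ppf(1 - sel.forward_alpha, 1) == pytest.approx(3.841,
                                                                   abs=1e-3)
        assert chi2.ppf(1 - sel.backward_alpha, 1) == pytest.approx(6.635,
                                                                    abs=1e-3)
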