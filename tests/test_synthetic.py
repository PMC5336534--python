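import numpy as np
import pandas as pd
import pytest

import hpmcerode as h
from hpmcerode.synthetic import apply_stop_rule, default_invitro_times


class TestInVitroDesign:
    design = h.generate_invitro_design()

    def test_design_counts(self):
        assert len(self.design) == 69  # 23 cells in triplicate
        cells = self.design.drop(columns="replicate").drop_duplicates()
        assert len(cells) == 23
        assert int(self.design["previously_published"].sum()) == 24

    def test_no_gastric_low_ionic_cells(self):
        bad = self.design[(self.design["ph"] == 1.2)
                          & (self.design["ionic_mosm"] == 98.0)]
        assert bad.empty

    def test_previously_published_cells_all_at_50_rpm(self):
        prev = self.design[self.design["previously_published"]]
        assert set(prev["rpm"]) == {50}
        assert set(prev["formulation"]) == {"F1", "F2", "F3", "F4"}

    def test_sampling_grid_spans_release_range(self):
        assert default_invitro_times("F1")[-1] == 16.0
        assert default_invitro_times("F3")[-1] == 10.0
        assert np.all(np.diff(default_invitro_times("F2")) == 0.5)


class TestInVitroSimulation:
    def test_no_noise_no_btv_equals_typical_profiles(self):
        X, y = h.simulate_invitro_dataset(
            params={"om_btv": 0.0, "sigma_add": 1e-12}, seed=0,
            times=np.array([1.0, 3.0, 6.0]))
        typical = h.InVitroErosionModel().predict(
            X, params={**h.INVITRO_DEFAULTS, "om_btv": 0.0})
        assert np.allclose(y, typical, atol=1e-6)

    def test_seed_reproducibility_byte_identical(self):
        X1, y1 = h.simulate_invitro_dataset(seed=9)
        X2, y2 = h.simulate_invitro_dataset(seed=9)
        assert X1.equals(X2) and np.array_equal(y1, y2)

    def test_missing_fraction_drops_rows(self):
        X_full, _ = h.simulate_invitro_dataset(seed=1)
        X_mar, _ = h.simulate_invitro_dataset(seed=1, missing_fraction=0.17)
        frac = 1.0 - len(X_mar) / len(X_full)
        assert frac == pytest.approx(0.17, abs=0.03)


class TestTransit:
    config = h.TransitConfig()

    def test_segment_order_and_truncation(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rec = h.generate_gi_transit("fasting", self.config, rng)
            assert 0 <= rec.si_entry <= 14.0
            if rec.colon_entry is not None:
                assert rec.colon_entry >= rec.si_entry
                assert rec.colon_entry <= 14.0

    def test_postprandial_gastric_residence_dominates_fasting(self):
        rng = np.random.default_rng(1)
        fast = [h.generate_gi_transit("fasting", self.config, rng).si_entry
                for _ in range(1000)]
        fed = [h.generate_gi_transit("postprandial", self.config,
                                     rng).si_entry for _ in range(1000)]
        assert np.mean(fed) > np.mean(fast)

    def test_unknown_prandial_rejected(self):
        with pytest.raises(ValueError):
            h.generate_gi_transit("brunch", self.config,
                                  np.random.default_rng(0))


class TestObservationSchedule:
    def test_grid_avoids_meal_break_windows(self):
        grid = h.observation_grid(h.TransitConfig())
        for lo, hi in ((4.0, 4.5), (6.0, 6.5), (10.0, 10.5)):
            assert not np.any((grid > lo) & (grid <= hi))
        assert grid[0] == 0.5 and grid[-1] == 14.0

    def test_stop_rule_examples(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        keep = apply_stop_rule(times, np.array([50.0, 80.0, 90.0, 100.0]),
                               dose=140.0, threshold=0.60)
        # cut at 84 mg: keep through the first crossing (90), drop 100
        assert keep.tolist() == [True, True, True, False]
        assert apply_stop_rule(times, np.array([10.0, 20.0, 30.0, 40.0]),
                               140.0, 0.60).all()
        first = apply_stop_rule(times, np.array([90.0, 95.0, 99.0, 100.0]),
                                140.0, 0.60)
        assert first.tolist() == [True, False, False, False]


class TestInVivoSimulation:
    def test_design_structure(self):
        X, y, gi = h.simulate_invivo_dataset(seed=2)
        assert X["subject"].nunique() == 5
        assert set(X["occasion"]) == {1, 2, 3, 4, 5, 6}
        combos = X.groupby("occasion")[["formulation", "prandial"]].first()
        assert combos.loc[1].tolist() == ["F1", "fasting"]
        assert combos.loc[4].tolist() == ["F3", "postprandial"]
        assert combos.loc[6].tolist() == ["F4", "postprandial"]

    def test_no_observation_in_meal_gaps_and_censoring_applied(self):
        X, y, gi = h.simulate_invivo_dataset(seed=2)
        for lo, hi in ((4.0, 4.5), (6.0, 6.5), (10.0, 10.5)):
            assert not np.any((X["time_h"] > lo) & (X["time_h"] <= hi))
        # at most one observation at/after the 60% threshold per occasion
        df = X.copy()
        df["dv"] = y
        df["dose"] = df["formulation"].map(
            lambda f: h.FORMULATIONS[f].hpmc_dose)
        for _, grp in df.groupby(["subject", "occasion"]):
            above = (grp.sort_values("time_h")["dv"].to_numpy()
                     >= 0.60 * grp["dose"].iloc[0])
            assert above[:-1].sum() == 0 or not above[:-1].any()

    def test_zero_variability_matches_typical_predictions(self):
        X, y, gi = h.simulate_invivo_dataset(
            seed=5, invivo_params={"om_bsv": 0.0, "om_bov": 0.0,
                                   "sigma_add": 1e-9, "sigma_prop": 1e-12})
        m = h.InVivoErosionModel()
        pred = m.predict(X, gi, params=dict(h.INVIVO_DEFAULTS),
                         ph_mode="recorded")
        assert np.allclose(y, pred, atol=1e-5)

    def test_gi_records_carry_ph_draws(self):
        _, _, gi = h.simulate_invivo_dataset(seed=2)
        assert {"subject", "occasion", "segment", "entry_time_h",
                "ph"} <= set(gi.columns)
        assert gi["ph"].between(0.5, 9.0).all()
        stomach = gi[gi["segment"] == "stomach"]
        fed = stomach[stomach["prandial"] == "postprandial"]["ph"]
        fast = stomach[stomach["prandial"] == "fasting"]["ph"]
        assert fed.mean() > fast.mean()

    def test_replication_extends_subjects(self):
        X, _, _ = h.simulate_invivo_dataset(seed=2, n_replicates=2)
        assert X["subject"].nunique() == 10
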