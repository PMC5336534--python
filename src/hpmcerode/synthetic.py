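"""Synthetic datasets emulating the in vitro and in vivo study designs.

The in vitro design reproduces the 23 USP2 formulation-condition cells
(each run in triplicate, 8 cells carried over from an earlier
publication) spanning gastric- and intestinal-like media and paddle
speeds of 25-150 rpm.  The in vivo generator emulates the magnetic
marker monitoring (MMM) crossover study: 5 subjects x 6 occasions
(formulations F1/F2 fasting, F3/F4 under both prandial statuses),
observations every 30 min up to 14 h with meal breaks at +4, +6 and
+10 h, and censoring once ~60% of the HPMC dose is released.

GI transit records are drawn from a configurable stand-in for a
compartmental transit model: gastric residence is exponential when
fasting and log-normal (longer) postprandially, and the
small-intestinal transit is log-normal.  The distribution families and
parameters are package assumptions, chosen to give realistic fasting
(~0.7 h) and postprandial (~3.5 h) gastric residence and ~3.5 h
small-intestinal transit; they are configurable and not fitted to any
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .environment import (GILocationRecord, PhPrior, RpmParams,
                          draw_segment_ph, segment_small_intestine)
from .estimation import ErrorModel
from .estimators import (INVITRO_DEFAULTS, INVIVO_DEFAULTS,
                         InVitroErosionModel, InVivoErosionModel)
from .formulations import FORMULATIONS

#: Table of in vitro design cells: (formulation, pH, ionic strength
#: mOsm/kg, rpm, previously published).  23 unique cells; the flagged
#: cells (all at 50 rpm) contribute the 24 carried-over profiles.
_INVITRO_CELLS: tuple[tuple[str, float, float, int, bool], ...] = (
    # pH 6.8, low ionic strength (98 mOsm/kg)
    ("F1", 6.8, 98.0, 50, True),
    ("F1", 6.8, 98.0, 100, False),
    ("F1", 6.8, 98.0, 150, False),
    ("F2", 6.8, 98.0, 25, False),
    ("F2", 6.8, 98.0, 50, True),
    ("F3", 6.8, 98.0, 25, False),
    ("F3", 6.8, 98.0, 50, True),
    ("F3", 6.8, 98.0, 100, False),
    ("F3", 6.8, 98.0, 150, False),
    ("F4", 6.8, 98.0, 50, True),
    ("F4", 6.8, 98.0, 100, False),
    # pH 1.2, high ionic strength (232 mOsm/kg)
    ("F1", 1.2, 232.0, 25, False),
    ("F1", 1.2, 232.0, 50, True),
    ("F1", 1.2, 232.0, 150, False),
    ("F2", 1.2, 232.0, 50, True),
    ("F2", 1.2, 232.0, 100, False),
    ("F3", 1.2, 232.0, 25, False),
    ("F3", 1.2, 232.0, 50, True),
    ("F3", 1.2, 232.0, 150, False),
    ("F4", 1.2, 232.0, 50, True),
    # pH 6.8, high ionic strength (232 mOsm/kg)
    ("F1", 6.8, 232.0, 50, False),
    ("F2", 6.8, 232.0, 50, False),
    ("F3", 6.8, 232.0, 50, False),
)


def generate_invitro_design() -> pd.DataFrame:
    """The triplicated USP2 design: 69 rows, one per tablet profile."""
    rows = []
    for form, ph, ionic, rpm, prev in _INVITRO_CELLS:
        for rep in range(1, 4):
            rows.append({"formulation": form, "ph": ph,
                         "ionic_mosm": ionic, "rpm": rpm,
                         "replicate": rep, "previously_published": prev})
    return pd.DataFrame(rows)


def default_invitro_times(formulation: str) -> np.ndarray:
    """Sampling grid: every 0.5 h, to 16 h for the slow-eroding
    high-MK4M formulations (F1, F2) and to 10 h for F3 and F4."""
    t_max = 16.0 if formulation in ("F1", "F2") else 10.0
    return np.arange(0.5, t_max + 1e-9, 0.5)


def simulate_invitro_dataset(
    design: Optional[pd.DataFrame] = None,
    params: Optional[dict] = None,
    seed: int = 0,
    missing_fraction: float = 0.0,
    times: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate noisy triplicate release profiles over the design.

    Per tablet: draw a log-normal between-tablet effect on Vmax,
    compute the covariate-adjusted release profile and add additive
    measurement noise; optionally drop a fraction of observations at
    random (missing at random).  Returns ``(X, y)`` in the long-format
    dialect used by the estimators.
    """
    design = generate_invitro_design() if design is None else design
    params = {**INVITRO_DEFAULTS, **(params or {})}
    rng = np.random.default_rng(seed)
    model = InVitroErosionModel()
    rows = []
    for i, cell in design.reset_index(drop=True).iterrows():
        t = default_invitro_times(cell["formulation"]) if times is None \
            else np.asarray(times, dtype=float)
        uid = f"{cell['formulation']}_pH{cell['ph']}_i{cell['ionic_mosm']:g}" \
              f"_r{cell['rpm']}_rep{cell['replicate']}"
        for ti in t:
            rows.append({"unit_id": uid, "time_h": float(ti),
                         "formulation": cell["formulation"],
                         "ph": float(cell["ph"]),
                         "rpm": float(cell["rpm"]),
                         "ionic_mosm": float(cell["ionic_mosm"]),
                         "replicate": int(cell["replicate"])})
    X = pd.DataFrame(rows)
    y = model.simulate(X, rng, params=params)
    if missing_fraction > 0.0:
        keep = rng.random(len(X)) >= missing_fraction
        X, y = X[keep].reset_index(drop=True), y[keep]
    return X, y


# ---------------------------------------------------------------------------
# in vivo design


@dataclass(frozen=True)
class TransitConfig:
    """Stand-in GI-transit distributions and the MMM schedule.

    Gastric residence: exponential (mean ``fasting_gastric_mean_h``)
    when fasting, log-normal (median ``fed_gastric_median_h``, log-SD
    ``fed_gastric_log_sd``) postprandially.  Small-intestinal transit:
    log-normal.  Observations every ``obs_interval_h`` up to
    ``horizon_h`` excluding the meal-break windows.
    """

    fasting_gastric_mean_h: float = 0.7
    fed_gastric_median_h: float = 3.5
    fed_gastric_log_sd: float = 0.35
    si_transit_median_h: float = 3.5
    si_transit_log_sd: float = 0.35
    horizon_h: float = 14.0
    obs_interval_h: float = 0.5
    meal_gaps: tuple[tuple[float, float], ...] = (
        (4.0, 4.5), (6.0, 6.5), (10.0, 10.5))


@dataclass(frozen=True)
class InVivoDesign:
    """Crossover design: occasion -> (formulation, prandial status)."""

    n_subjects: int = 5
    occasions: tuple[tuple[str, str], ...] = (
        ("F1", "fasting"), ("F2", "fasting"),
        ("F3", "fasting"), ("F3", "postprandial"),
        ("F4", "fasting"), ("F4", "postprandial"))


def generate_gi_transit(prandial: str, config: TransitConfig,
                        rng: np.random.Generator,
                        subject: int = 0, occasion: int = 0
                        ) -> GILocationRecord:
    """Draw one stomach -> small intestine -> colon transit record."""
    if prandial == "fasting":
        ge = rng.exponential(config.fasting_gastric_mean_h)
    elif prandial == "postprandial":
        ge = rng.lognormal(np.log(config.fed_gastric_median_h),
                           config.fed_gastric_log_sd)
    else:
        raise ValueError(f"unknown prandial status {prandial!r}")
    sitt = rng.lognormal(np.log(config.si_transit_median_h),
                         config.si_transit_log_sd)
    ge = min(ge, config.horizon_h)
    colon = ge + sitt
    return GILocationRecord(
        subject=subject, occasion=occasion, prandial=prandial,
        si_entry=float(ge),
        colon_entry=float(colon) if colon < config.horizon_h else None,
        record_end=config.horizon_h)


def observation_grid(config: TransitConfig) -> np.ndarray:
    """MMM observation times: the 30-min grid minus meal-break windows."""
    t = np.arange(config.obs_interval_h, config.horizon_h + 1e-9,
                  config.obs_interval_h)
    for lo, hi in config.meal_gaps:
        t = t[(t <= lo) | (t > hi)]
    return t


def apply_stop_rule(times: np.ndarray, dv: np.ndarray, dose: float,
                    threshold: float = 0.60) -> np.ndarray:
    """Boolean mask of observations retained under the MMM stopping
    rule: everything up to and including the first crossing of the
    released-fraction threshold."""
    frac = np.asarray(dv, dtype=float) / dose
    above = np.nonzero(frac >= threshold)[0]
    keep = np.ones(len(times), dtype=bool)
    if above.size:
        keep[above[0] + 1:] = False
    return keep


def simulate_invivo_dataset(
    design: Optional[InVivoDesign] = None,
    invitro_params: Optional[dict] = None,
    invivo_params: Optional[dict] = None,
    config: Optional[TransitConfig] = None,
    seed: int = 0,
    n_replicates: int = 1,
    censor_fraction: float = 0.60,
    segmentation: str = "fixed_offset_1h",
    ph_prior: Optional[PhPrior] = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Simulate the MMM crossover study.

    Per subject-occasion: draw a GI transit record, segment the small
    intestine, draw one pH per segment from the priors, build the
    environment, simulate the release profile with between-subject and
    between-occasion variability on the 30-min grid (minus meal
    breaks), add combined-error noise and apply the stopping rule.

    ``n_replicates`` repeats the whole design with new subjects (ids
    continue) to enlarge the dataset.  Returns ``(X, y, gi_records)``;
    ``gi_records`` holds one row per subject-occasion-segment with the
    drawn pH, ready to feed :class:`InVivoErosionModel.fit`.
    """
    design = design or InVivoDesign()
    config = config or TransitConfig()
    prior = ph_prior or PhPrior()
    ivt = {**INVITRO_DEFAULTS, **(invitro_params or {})}
    ivv = {**INVIVO_DEFAULTS, **(invivo_params or {})}
    rng = np.random.default_rng(seed)
    error = ErrorModel("combined", sigma_add=ivv["sigma_add"],
                       sigma_prop=ivv["sigma_prop"])
    rpm = RpmParams(ivv["rpm_stomach"], ivv["rpm_proximal_si"],
                    ivv["rpm_distal_si"], ivv["rpm_colon"])
    # an unfitted estimator is used purely as the prediction engine
    engine = InVivoErosionModel(invitro_params=ivt, segmentation=segmentation)
    theta = engine._theta()
    grid = observation_grid(config)

    obs_rows, dv_out, gi_rows = [], [], []
    subj_id = 0
    for _rep in range(n_replicates):
        for _s in range(design.n_subjects):
            subj_id += 1
            eta_s = rng.normal(0.0, ivv["om_bsv"])
            for occ_no, (form_name, prandial) in enumerate(
                    design.occasions, start=1):
                form = FORMULATIONS[form_name]
                rec = generate_gi_transit(prandial, config, rng,
                                          subject=subj_id, occasion=occ_no)
                seg_tl = segment_small_intestine(rec, segmentation)
                segs = []
                for name, entry in zip(seg_tl.segments, seg_tl.entry_times):
                    ph = draw_segment_ph(name, prandial, prior, rng)
                    segs.append((float(entry), name, ph))
                    gi_rows.append({"subject": subj_id, "occasion": occ_no,
                                    "prandial": prandial,
                                    "formulation": form_name,
                                    "segment": name,
                                    "entry_time_h": float(entry),
                                    "ph": ph})
                eta = eta_s + rng.normal(0.0, ivv["om_bov"])
                occ = {
                    "times": grid,
                    "entries": np.array([s[0] for s in segs]),
                    "segnames": [s[1] for s in segs],
                    "vmax_base": np.array([
                        theta["tv_vmax"]
                        * max(1.0 + theta["s_ph_vmax"] * (s[2] - 6.8), 1e-6)
                        * max(1.0 + theta["s_dcp_vmax"]
                              * (form.dcp_frac - 57.6), 1e-6)
                        * (1.0 - form.mk4m_frac
                           / (theta["mk4m50_vmax"] + form.mk4m_frac))
                        for s in segs]),
                    "kms": np.array([
                        max(theta["tv_km"]
                            * max(1.0 + theta["s_ph_km"] * (s[2] - 6.8), 1e-6)
                            * max(1.0 + theta["s_dcp_km"]
                                  * (form.dcp_frac - 57.6), 1e-6), 1e-9)
                        for s in segs]),
                    "dose": form.hpmc_dose,
                }
                params = {"rpm_stomach": rpm.rpm_stomach,
                          "rpm_proximal_si": rpm.rpm_proximal_si,
                          "rpm_distal_si": rpm.rpm_distal_si,
                          "rpm_colon": rpm.rpm_colon, "tlag": ivv["tlag"]}
                pred = engine._occ_released(params, occ, theta, eta)
                dv = pred + rng.normal(0.0, error.sd(pred))
                keep = apply_stop_rule(grid, dv, form.hpmc_dose,
                                       censor_fraction)
                for ti, yi in zip(grid[keep], dv[keep]):
                    obs_rows.append({"subject": subj_id,
                                     "occasion": occ_no,
                                     "time_h": float(ti),
                                     "formulation": form_name,
                                     "prandial": prandial})
                    dv_out.append(float(yi))
    X = pd.DataFrame(obs_rows)
    return X, np.asarray(dv_out), pd.DataFrame(gi_rows)


def write_provenance(path, seed: int, config) -> None:
    """Record seed and configuration next to an emitted dataset."""
    payload = {"seed": int(seed)}
    if config is not None:
        payload["config"] = asdict(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
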