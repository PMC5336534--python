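"""End-to-end analysis workflows.

Three staged entry points mirror the analysis sequence:

1. :func:`run_invitro_workflow` -- fit both structural candidates to
   USP2 dissolution data, compare AIC, optionally run stepwise
   covariate selection, and report the selected fit.
2. :func:`run_invivo_workflow` -- carry the in vitro typical values
   and covariate coefficients forward (fixed) and estimate the GI
   mechanical stresses, in vivo lag, variability and residual error,
   honoring the formulation-F4-fasting exclusion.
3. :func:`run_prediction_simulation` -- simulate release profiles and
   GI-location occupancy for each formulation x prandial status from
   freshly drawn transit records.

Estimation is strictly sequential (in vitro then in vivo); there is no
joint-fit mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .environment import PhPrior, draw_segment_ph, segment_small_intestine
from .estimators import (INVITRO_DEFAULTS, INVIVO_DEFAULTS,
                         InVitroErosionModel, InVivoErosionModel,
                         StepwiseCovariateSelector)
from .formulations import FORMULATIONS
from .synthetic import TransitConfig, generate_gi_transit, observation_grid


@dataclass
class WorkflowConfig:
    """Stage toggles and options shared by the workflow runners."""

    fit_structural: bool = True
    run_scm: bool = False
    run_vpc: bool = False
    segmentation: str = "fixed_offset_1h"
    exclude: tuple[tuple[str, str], ...] = (("F4", "fasting"),)
    seed: int = 0
    compute_se: bool = True
    maxiter: int = 300
    output_dir: Optional[str] = None


def _write_manifest(outdir: Path, config: WorkflowConfig, extra: dict):
    manifest = {"seed": config.seed, "config": vars(config).copy(), **extra}
    manifest["config"].pop("output_dir", None)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_invitro_workflow(X: pd.DataFrame, y,
                         config: Optional[WorkflowConfig] = None) -> dict:
    """Structural-model comparison, optional SCM, and the selected fit.

    Returns a report dict with both AICs, the selected structural
    model, the final fit and (optionally) the SCM path.
    """
    config = config or WorkflowConfig()
    report: dict = {"stages": []}
    if not config.fit_structural and not config.run_scm:
        return report

    if config.fit_structural:
        mm = InVitroErosionModel(structural="michaelis-menten",
                                 compute_se=config.compute_se,
                                 maxiter=config.maxiter).fit(X, y)
        mech = InVitroErosionModel(structural="mechanism",
                                   compute_se=False,
                                   maxiter=config.maxiter).fit(X, y)
        selected = "michaelis-menten" if mm.aic_ <= mech.aic_ \
            else "mechanism"
        report.update({
            "aic_michaelis_menten": mm.aic_, "aic_mechanism": mech.aic_,
            "selected_structural": selected,
            "fit": mm.result_.to_dict() if selected == "michaelis-menten"
            else mech.result_.to_dict(),
        })
        report["model"] = mm if selected == "michaelis-menten" else mech
        report["stages"].append("structural_comparison")

    if config.run_scm:
        sel = StepwiseCovariateSelector(maxiter=config.maxiter).fit(X, y)
        report["scm_relations"] = [vars(r) for r in sel.relations_]
        report["scm_path"] = [
            {"action": s.action, "relation": vars(s.relation),
             "delta_ofv": s.delta_ofv, "p": s.p_value}
            for s in sel.path_]
        report["model"] = sel.final_model_
        report["fit"] = sel.final_model_.result_.to_dict()
        report["stages"].append("scm")

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items() if k != "model"}
        with open(outdir / "invitro_report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=str)
        _write_manifest(outdir, config, {"stage": "invitro"})
    return report


def run_invivo_workflow(X: pd.DataFrame, y, gi_records: pd.DataFrame,
                        invitro_params: Optional[dict] = None,
                        config: Optional[WorkflowConfig] = None) -> dict:
    """Fit the in vivo model with in vitro parameters fixed.

    ``invitro_params`` may come from a fitted in vitro model
    (``model.params_``); defaults to the package's selected-model
    values.
    """
    config = config or WorkflowConfig()
    model = InVivoErosionModel(invitro_params=invitro_params,
                               segmentation=config.segmentation,
                               exclude=config.exclude,
                               compute_se=config.compute_se,
                               maxiter=config.maxiter)
    model.fit(X, y, gi_records)
    report = {
        "fit": model.result_.to_dict(),
        "rpm": {"stomach": model.params_["rpm_stomach"],
                "proximal_si": model.params_["rpm_proximal_si"],
                "distal_si": model.params_["rpm_distal_si"],
                "colon": model.params_["rpm_colon"]},
        "tlag_h": model.params_["tlag"],
        "bsv_cv_percent": model.bsv_cv_percent(),
        "bov_cv_percent": model.bov_cv_percent(),
        "n_excluded_occasions": len(model.excluded_),
        "model": model,
    }
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items() if k != "model"}
        with open(outdir / "invivo_report.json", "w") as fh:
            json.dump(serializable, fh, indent=2, default=str)
        _write_manifest(outdir, config, {"stage": "invivo"})
    return report


@dataclass
class SimulationSummary:
    """Median and 90% prediction interval of simulated release, plus
    GI-location occupancy fractions, per formulation x prandial."""

    times: np.ndarray
    release: pd.DataFrame    # formulation, prandial, time_h, p5, p50, p95
    occupancy: pd.DataFrame  # prandial, time_h, segment, fraction


def run_prediction_simulation(
    invitro_params: Optional[dict] = None,
    invivo_params: Optional[dict] = None,
    transit_config: Optional[TransitConfig] = None,
    formulations: Sequence[str] = ("F1", "F2", "F3", "F4"),
    prandial_states: Sequence[str] = ("fasting", "postprandial"),
    n_profiles: int = 1000,
    seed: int = 0,
    zero_variability: bool = False,
) -> SimulationSummary:
    """Forward-simulate in vivo release under fresh transit records.

    For each formulation and prandial status, ``n_profiles`` profiles
    are simulated (transit draw, segment pH draws, between-subject and
    between-occasion variability unless ``zero_variability``), then
    summarized as the pointwise median and 90% prediction interval.
    Residual measurement error is not added: the summary describes the
    erosion process, not the assay.
    """
    tc = transit_config or TransitConfig()
    ivt = {**INVITRO_DEFAULTS, **(invitro_params or {})}
    ivv = {**INVIVO_DEFAULTS, **(invivo_params or {})}
    rng = np.random.default_rng(seed)
    prior = PhPrior()
    engine = InVivoErosionModel(invitro_params=ivt)
    theta = engine._theta()
    grid = observation_grid(tc)
    rpm_lookup = {"rpm_stomach": ivv["rpm_stomach"],
                  "rpm_proximal_si": ivv["rpm_proximal_si"],
                  "rpm_distal_si": ivv["rpm_distal_si"],
                  "rpm_colon": ivv["rpm_colon"], "tlag": ivv["tlag"]}

    release_rows, occ_rows = [], []
    for prandial in prandial_states:
        # transit records shared across formulations per prandial state
        occupancy = np.zeros((grid.size, 4))
        seg_order = ["stomach", "proximal_SI", "distal_SI", "colon"]
        records = []
        for _ in range(n_profiles):
            if zero_variability:
                # deterministic transit at the distributions' centers
                ge = tc.fasting_gastric_mean_h if prandial == "fasting" \
                    else tc.fed_gastric_median_h
                from .environment import GILocationRecord
                colon = ge + tc.si_transit_median_h
                rec = GILocationRecord(
                    subject=0, occasion=0, prandial=prandial,
                    si_entry=ge,
                    colon_entry=colon if colon < tc.horizon_h else None,
                    record_end=tc.horizon_h)
            else:
                rec = generate_gi_transit(prandial, tc, rng)
            seg_tl = segment_small_intestine(rec, "fixed_offset_1h")
            segs = []
            for name, entry in zip(seg_tl.segments, seg_tl.entry_times):
                ph = prior.lookup(name, prandial)[0] if zero_variability \
                    else draw_segment_ph(name, prandial, prior, rng)
                segs.append((float(entry), name, ph))
            records.append(segs)
            entries = [s[0] for s in segs] + [np.inf]
            for gi_idx, name in enumerate(seg_tl.segments):
                sel = (grid >= entries[gi_idx]) & (grid < entries[gi_idx + 1])
                occupancy[sel, seg_order.index(name)] += 1
        occupancy /= n_profiles
        for ti, row in zip(grid, occupancy):
            for name, frac in zip(seg_order, row):
                occ_rows.append({"prandial": prandial, "time_h": float(ti),
                                 "segment": name, "fraction": float(frac)})

        for form_name in formulations:
            form = FORMULATIONS[form_name]
            sims = np.empty((n_profiles, grid.size))
            for k, segs in enumerate(records):
                eta = 0.0 if zero_variability else rng.normal(
                    0.0, np.hypot(ivv["om_bsv"], ivv["om_bov"]))
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
                            * max(1.0 + theta["s_ph_km"] * (s[2] - 6.8),
                                  1e-6)
                            * max(1.0 + theta["s_dcp_km"]
                                  * (form.dcp_frac - 57.6), 1e-6), 1e-9)
                        for s in segs]),
                    "dose": form.hpmc_dose,
                }
                sims[k] = engine._occ_released(rpm_lookup, occ, theta, eta)
            p5, p50, p95 = np.percentile(sims, [5, 50, 95], axis=0)
            for i, ti in enumerate(grid):
                release_rows.append({"formulation": form_name,
                                     "prandial": prandial,
                                     "time_h": float(ti),
                                     "p5": float(p5[i]),
                                     "p50": float(p50[i]),
                                     "p95": float(p95[i])})
    return SimulationSummary(times=grid,
                             release=pd.DataFrame(release_rows),
                             occupancy=pd.DataFrame(occ_rows))
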