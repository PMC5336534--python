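"""Scikit-learn style estimators for tablet-erosion mixed-effects models.

Three estimators cover the analysis:

* :class:`InVitroErosionModel` -- fits a structural erosion model
  (Michaelis-Menten or mechanism-based) with a configurable
  multiplicative covariate model and between-tablet variability to
  long-format USP2 dissolution data.
* :class:`InVivoErosionModel` -- keeps the in vitro structural and
  covariate parameters fixed and estimates the gastrointestinal
  mechanical stresses (USP2 rpm equivalents), the in vivo lag time,
  between-subject/between-occasion variability and the residual error
  from tablet-location-resolved release data.
* :class:`StepwiseCovariateSelector` -- forward-inclusion /
  backward-deletion covariate selection around
  :class:`InVitroErosionModel`.

Long-format data conventions: ``X`` is a DataFrame with one row per
observation and ``y`` the released HPMC in mg.  In vitro ``X`` needs
columns ``unit_id, time_h, formulation, ph, rpm`` (optionally
``ionic_mosm``); in vivo ``X`` needs ``subject, occasion, time_h,
formulation, prandial`` plus a GI-record table passed to ``fit``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .covariates import REF_DCP, REF_PH, REF_RPM
from .environment import (PhPrior, RpmParams, GILocationRecord,
                          segment_small_intestine, STOMACH, PROXIMAL_SI,
                          DISTAL_SI, COLON, SMALL_INTESTINE)
from .estimation import (ErrorModel, FitResult, Param, ParamSet,
                         fit_population, laplace_nested_m2ll,
                         laplace_scalar_m2ll, omega_to_cv_percent)
from .formulations import FORMULATIONS, Formulation
from .model_core import _lambertw_of_exp

_MULT_FLOOR = 1e-6


@dataclass(frozen=True)
class Relation:
    """One covariate-parameter relation in the multiplicative model."""

    cov: str     # "rpm" | "ph" | "dcp" | "mk4m" | "ionic"
    target: str  # "vmax" | "km" (MM) or "r" | "gamma" (mechanism)
    form: str    # "linear" | "power" | "emax"

    @property
    def n_params(self) -> int:
        return 2 if self.form == "emax" else 1

    def param_names(self) -> list[str]:
        if self.form == "linear":
            return [f"s_{self.cov}_{self.target}"]
        if self.form == "power":
            return [f"pwr_{self.cov}_{self.target}"]
        return [f"emax_{self.cov}_{self.target}",
                f"{self.cov}50_{self.target}"]


#: Relations of the selected in vitro model: linear mechanical-stress,
#: pH and DCP effects plus saturable MK4M inhibition on Vmax; linear
#: pH and DCP effects on Km.
FINAL_RELATIONS: tuple[Relation, ...] = (
    Relation("rpm", "vmax", "linear"),
    Relation("ph", "vmax", "linear"),
    Relation("dcp", "vmax", "linear"),
    Relation("mk4m", "vmax", "emax"),
    Relation("ph", "km", "linear"),
    Relation("dcp", "km", "linear"),
)

#: Package defaults for the in vitro population parameters (the
#: selected-model estimates; also the generating truth of the
#: synthetic-data module).
INVITRO_DEFAULTS: dict[str, float] = {
    "tv_vmax": 22.0,
    "tv_km": 34.2,
    "tlag": 0.179,
    "s_rpm_vmax": 0.0115,
    "s_ph_vmax": -0.0319,
    "s_dcp_vmax": 0.0332,
    "emax_mk4m_vmax": -1.0,
    "mk4m50_vmax": 18.7,
    "s_ph_km": 0.0935,
    "s_dcp_km": 0.0522,
    "om_btv": 0.0596,
    "sigma_add": 1.95,
}

#: In vivo population defaults (segment stresses in USP2 rpm
#: equivalents, lag, variability and combined error).
INVIVO_DEFAULTS: dict[str, float] = {
    "rpm_stomach": 39.5,
    "rpm_proximal_si": 93.3,
    "rpm_distal_si": 31.1,
    "rpm_colon": 9.99,
    "tlag": 0.410,
    "om_bsv": 0.148,
    "om_bov": 0.154,
    "sigma_prop": 0.142,
    "sigma_add": 1.86,
}

_REFS = {"rpm": REF_RPM, "ph": REF_PH, "dcp": REF_DCP, "mk4m": 0.0}


def _relation_multiplier(rel: Relation, params: dict, cov_val: float,
                         ref: float) -> float:
    if rel.form == "linear":
        m = 1.0 + params[f"s_{rel.cov}_{rel.target}"] * (cov_val - ref)
    elif rel.form == "power":
        m = (cov_val / ref) ** params[f"pwr_{rel.cov}_{rel.target}"]
    else:
        emax = params[f"emax_{rel.cov}_{rel.target}"]
        cov50 = params[f"{rel.cov}50_{rel.target}"]
        m = 1.0 + emax * cov_val / (cov50 + cov_val)
    return m if m > _MULT_FLOOR else _MULT_FLOOR


def _mm_released(times: np.ndarray, vmax: float, km: float, dose: float,
                 tlag: float) -> np.ndarray:
    """Single-segment Michaelis-Menten released amounts (lean path)."""
    out = np.zeros_like(times)
    act = times > tlag
    if np.any(act):
        dt = times[act] - tlag
        log_x = np.log(dose / km) + (dose - vmax * dt) / km
        out[act] = dose - km * _lambertw_of_exp(log_x)
    return np.clip(out, 0.0, dose)


def _mechanism_released(times: np.ndarray, r: float, gamma: float,
                        dose: float, weight: float,
                        tlag: float) -> np.ndarray:
    """Single-segment power-law released amounts."""
    out = np.zeros_like(times)
    act = times > tlag
    if np.any(act):
        dt = times[act] - tlag
        c = r * (weight / dose) ** (gamma - 1.0)
        if abs(gamma - 1.0) < 1e-12:
            h = dose * np.exp(-c * dt)
        else:
            base = np.maximum(dose ** (1.0 - gamma)
                              - (1.0 - gamma) * c * dt, 0.0)
            with np.errstate(divide="ignore"):
                h = base ** (1.0 / (1.0 - gamma))
            if gamma > 1.0:
                h = np.where(base > 0, h, dose)
        out[act] = dose - h
    return np.clip(out, 0.0, dose)


def _mm_released_chained(times: np.ndarray, entries: np.ndarray,
                         vmaxs: np.ndarray, kms: np.ndarray, dose: float,
                         tlag: float) -> np.ndarray:
    """Chained-segment Michaelis-Menten released amounts.

    ``entries`` are the segment entry times (first 0); parameters are
    constant within a segment and the state carries across boundaries.
    Release runs from ``tlag``.
    """
    out = np.zeros_like(times)
    act = times > tlag
    if not np.any(act):
        return out
    t_act = times[act]
    t_end = float(t_act[-1])
    rel = np.empty_like(t_act)
    h = float(dose)
    a = tlag
    for i in range(entries.size):
        b = float(entries[i + 1]) if i + 1 < entries.size else np.inf
        if b <= tlag:
            continue
        b = min(b, t_end)
        vmax, km = float(vmaxs[i]), float(kms[i])
        sel = (t_act > a) & (t_act <= b)
        if np.any(sel):
            log_x = np.log(h / km) + (h - vmax * (t_act[sel] - a)) / km
            rel[sel] = dose - km * _lambertw_of_exp(log_x)
        if b >= t_end:
            break
        log_x = np.log(h / km) + (h - vmax * (b - a)) / km
        h = float(km * _lambertw_of_exp(np.array([log_x]))[0])
        if h <= 1e-12:
            rel[t_act > b] = dose
            a = b
            h = 1e-12
            continue
        a = b
    out[act] = np.clip(rel, 0.0, dose)
    return out


def _as_formulation(value, registry: dict[str, Formulation]) -> Formulation:
    if isinstance(value, Formulation):
        return value
    try:
        return registry[str(value)]
    except KeyError:
        raise ValueError(f"unknown formulation {value!r}") from None


# ---------------------------------------------------------------------------
# in vitro estimator


class InVitroErosionModel(BaseEstimator):
    """Mixed-effects erosion model for USP2 dissolution profiles.

    Parameters
    ----------
    structural : {"michaelis-menten", "mechanism"}
        Rate law for HPMC depletion.
    relations : sequence of Relation
        Multiplicative covariate-parameter relations.  Defaults to the
        selected model (``FINAL_RELATIONS``) for the Michaelis-Menten
        law and its mirror on the basal rate for the mechanism law.
    error : {"additive", "proportional", "combined"}
        Residual error family.
    btv : bool
        Include log-normal between-tablet variability on the rate
        parameter (Vmax or R).
    start : dict, optional
        Overrides for starting values (natural scale).
    fixed : dict, optional
        Parameters to hold fixed, name -> value.  Saturable-effect
        ``emax_*`` coefficients are fixed at -1 (full inhibition)
        unless listed here or freed via ``fix_emax=False``.
    compute_se : bool
        Compute sandwich standard errors after the fit.
    """

    def __init__(self, structural: str = "michaelis-menten",
                 relations: Optional[Sequence[Relation]] = None,
                 error: str = "additive", btv: bool = True,
                 start: Optional[dict] = None,
                 fixed: Optional[dict] = None,
                 fix_emax: bool = True,
                 compute_se: bool = True,
                 maxiter: int = 300,
                 formulations: Optional[dict] = None):
        self.structural = structural
        self.relations = relations
        self.error = error
        self.btv = btv
        self.start = start
        self.fixed = fixed
        self.fix_emax = fix_emax
        self.compute_se = compute_se
        self.maxiter = maxiter
        self.formulations = formulations

    # -- helpers ----------------------------------------------------------

    def _relations(self) -> tuple[Relation, ...]:
        if self.relations is not None:
            return tuple(self.relations)
        if self.structural == "michaelis-menten":
            return FINAL_RELATIONS
        return tuple(Relation(r.cov, "r", r.form)
                     for r in FINAL_RELATIONS if r.target == "vmax")

    def _build_paramset(self, ionic_median: float) -> tuple[ParamSet, dict]:
        start = dict(INVITRO_DEFAULTS)
        if self.structural == "mechanism":
            start.update({"r_basal": 0.2, "gamma": 1.0})
        start.setdefault("sigma_prop", 0.10)
        if self.start:
            start.update(self.start)
        fixed = dict(self.fixed or {})

        params: list[Param] = []
        if self.structural == "michaelis-menten":
            base = [("tv_vmax", "log"), ("tv_km", "log"), ("tlag", "log")]
        else:
            base = [("r_basal", "log"), ("gamma", "log"), ("tlag", "log")]
        for name, tr in base:
            params.append(Param(name, start[name], tr))
        for rel in self._relations():
            for pname in rel.param_names():
                if pname.startswith("emax_"):
                    val = start.get(pname, -1.0)
                    params.append(Param(pname, val, "identity",
                                        fixed=self.fix_emax))
                elif pname.startswith("s_"):
                    # slopes are O(0.01-0.1) per covariate unit
                    params.append(Param(pname, start.get(pname, 0.0),
                                        "identity", scale=0.01))
                elif pname.startswith("pwr_"):
                    params.append(Param(pname, start.get(pname, 0.0),
                                        "identity"))
                else:  # cov50
                    default = start.get(pname,
                                        max(_REFS.get(rel.cov, 1.0), 1.0))
                    if pname in start:
                        default = start[pname]
                    params.append(Param(pname, default, "log"))
        if self.btv:
            params.append(Param("om_btv", start["om_btv"], "log"))
        if self.error in ("additive", "combined"):
            params.append(Param("sigma_add", start["sigma_add"], "log"))
        if self.error in ("proportional", "combined"):
            params.append(Param("sigma_prop", start["sigma_prop"], "log"))

        for p in params:
            if p.name in fixed:
                p.value = float(fixed[p.name])
                p.fixed = True
        refs = dict(_REFS)
        refs["ionic"] = ionic_median
        return ParamSet(params), refs

    def _unit_features(self, X: pd.DataFrame) -> list[dict]:
        registry = self.formulations or FORMULATIONS
        units = []
        for uid, grp in X.groupby("unit_id", sort=True):
            form = _as_formulation(grp["formulation"].iloc[0], registry)
            units.append({
                "unit_id": uid,
                "idx": grp.index.to_numpy(),
                "times": grp["time_h"].to_numpy(dtype=float),
                "cov": {
                    "rpm": float(grp["rpm"].iloc[0]),
                    "ph": float(grp["ph"].iloc[0]),
                    "dcp": form.dcp_frac,
                    "mk4m": form.mk4m_frac,
                    "ionic": float(grp["ionic_mosm"].iloc[0])
                    if "ionic_mosm" in grp else 0.0,
                },
                "dose": form.hpmc_dose,
                "weight": form.tablet_weight,
            })
        return units

    def _unit_released(self, params: dict, unit: dict, refs: dict,
                       eta: float = 0.0) -> np.ndarray:
        mult = {"vmax": 1.0, "km": 1.0, "r": 1.0, "gamma": 1.0}
        for rel in self._relations():
            mult[rel.target] *= _relation_multiplier(
                rel, params, unit["cov"][rel.cov], refs.get(rel.cov, 0.0))
        if self.structural == "michaelis-menten":
            vmax = params["tv_vmax"] * mult["vmax"] * np.exp(eta)
            km = max(params["tv_km"] * mult["km"], 1e-9)
            return _mm_released(unit["times"], vmax, km, unit["dose"],
                                params["tlag"])
        r = params["r_basal"] * mult["r"] * np.exp(eta)
        gamma = params["gamma"] * mult["gamma"]
        return _mechanism_released(unit["times"], r, gamma, unit["dose"],
                                   unit["weight"], params["tlag"])

    def _error_model(self, params: dict) -> ErrorModel:
        return ErrorModel(self.error,
                          sigma_add=params.get("sigma_add", 0.0),
                          sigma_prop=params.get("sigma_prop", 0.0))

    # -- batched likelihood (all tablets at once) -------------------------

    def _batched_arrays(self, units: list[dict], dv: np.ndarray) -> dict:
        n = len(units)
        n_t = max(u["times"].size for u in units)
        T = np.zeros((n, n_t))
        DV = np.zeros((n, n_t))
        M = np.zeros((n, n_t), dtype=bool)
        for i, u in enumerate(units):
            k = u["times"].size
            T[i, :k] = u["times"]
            DV[i, :k] = dv[u["idx"]]
            M[i, :k] = True
        cov = {c: np.array([u["cov"][c] for u in units])
               for c in ("rpm", "ph", "dcp", "mk4m", "ionic")}
        return {"T": T, "DV": DV, "M": M, "cov": cov,
                "dose": np.array([u["dose"] for u in units]),
                "weight": np.array([u["weight"] for u in units]), "n": n}

    def _batched_multipliers(self, params: dict, B: dict,
                             refs: dict) -> tuple[np.ndarray, np.ndarray]:
        n = B["n"]
        m_rate = np.ones(n)
        m_other = np.ones(n)
        for rel in self._relations():
            cov = B["cov"][rel.cov]
            ref = refs.get(rel.cov, 0.0)
            if rel.form == "linear":
                m = 1.0 + params[f"s_{rel.cov}_{rel.target}"] * (cov - ref)
            elif rel.form == "power":
                m = (cov / ref) ** params[f"pwr_{rel.cov}_{rel.target}"]
            else:
                m = 1.0 + (params[f"emax_{rel.cov}_{rel.target}"] * cov
                           / (params[f"{rel.cov}50_{rel.target}"] + cov))
            m = np.maximum(m, _MULT_FLOOR)
            if rel.target in ("vmax", "r"):
                m_rate *= m
            else:
                m_other *= m
        return m_rate, m_other

    def _batched_released(self, params: dict, B: dict, refs: dict,
                          eta: np.ndarray) -> np.ndarray:
        m_rate, m_other = self._batched_multipliers(params, B, refs)
        T, dose = B["T"], B["dose"][:, None]
        dt = np.maximum(T - params["tlag"], 0.0)
        if self.structural == "michaelis-menten":
            vmax = (params["tv_vmax"] * m_rate * np.exp(eta))[:, None]
            km = np.maximum(params["tv_km"] * m_other, 1e-9)[:, None]
            log_x = np.log(dose / km) + (dose - vmax * dt) / km
            h = km * _lambertw_of_exp(log_x)
        else:
            r = (params["r_basal"] * m_rate * np.exp(eta))[:, None]
            gamma = np.maximum(params["gamma"] * m_other, 1e-9)[:, None]
            c = r * (B["weight"][:, None] / dose) ** (gamma - 1.0)
            base = dose ** (1.0 - gamma) - (1.0 - gamma) * c * dt
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(base > 0,
                             np.abs(base) ** (1.0 / (1.0 - gamma)),
                             np.where(gamma < 1.0, 0.0, dose))
            near1 = np.isclose(gamma, 1.0, atol=1e-10)
            if np.any(near1):
                h = np.where(near1, dose * np.exp(-c * dt), h)
        rel = np.clip(dose - h, 0.0, dose)
        return np.where(dt > 0.0, rel, 0.0)

    def _batched_laplace(self, params: dict, B: dict, refs: dict,
                         om2: float, error: ErrorModel,
                         eta0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-tablet -2 log marginal likelihood, all units at once."""
        M, DV = B["M"], B["DV"]

        def cll(eta: np.ndarray) -> np.ndarray:
            pred = self._batched_released(params, B, refs, eta)
            var = error.variance(pred)
            res = DV - pred
            return np.sum(np.where(M, np.log(2.0 * np.pi * var)
                                   + res * res / var, 0.0), axis=1)

        if om2 <= 0.0:
            return cll(np.zeros(B["n"])), np.zeros(B["n"])
        om = float(np.sqrt(om2))
        prior_const = np.log(2.0 * np.pi * om2)

        def g(eta: np.ndarray) -> np.ndarray:
            return cll(eta) + eta * eta / om2 + prior_const

        eta = eta0.copy()
        gx = g(eta)
        h = max(1e-2 * om, 1e-4)
        for _ in range(40):
            gp, gm = g(eta + h), g(eta - h)
            d1 = (gp - gm) / (2.0 * h)
            d2 = (gp + gm - 2.0 * gx) / (h * h)
            newton = -d1 / np.maximum(d2, 1e-12)
            # converged once the residual step is OFV-negligible
            conv = (np.abs(d1) < 1e-5) | ((d2 > 0) & (
                (np.abs(newton) < 1e-6 * om)
                | (np.abs(d1 * newton) < 2e-9)))
            if np.all(conv):
                break
            step = np.where(d2 > 1e-12, newton, -np.sign(d1) * om)
            step = np.clip(step, -5.0 * om, 5.0 * om)
            step = np.where(conv, 0.0, step)
            for _bt in range(15):
                gn = g(eta + step)
                bad = (gn > gx) & ~conv
                if not np.any(bad):
                    break
                step = np.where(bad, 0.5 * step, step)
            ok = gn <= gx
            moved = ok & ~conv & (np.abs(step) > 0)
            eta = np.where(ok, eta + step, eta)
            gx = np.where(ok, gn, gx)
            if not np.any(moved):
                break  # stalled at numerical precision
        gp, gm = g(eta + h), g(eta - h)
        curv = np.maximum((gp + gm - 2.0 * gx) / (h * h),
                          2e-3 / om2)
        m2ll = gx - np.log(2.0 * np.pi) + np.log(curv / 2.0)
        return m2ll, eta

    # -- estimator API ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "InVitroErosionModel":
        X = X.reset_index(drop=True)
        dv = np.asarray(y, dtype=float)
        if dv.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        units = self._unit_features(X)
        ionic_vals = [u["cov"]["ionic"] for u in units]
        paramset, refs = self._build_paramset(float(np.median(ionic_vals)))
        B = self._batched_arrays(units, dv)
        eta_state = {"eta": np.zeros(B["n"])}

        def unit_terms(x: np.ndarray) -> np.ndarray:
            params = paramset.unpack(x)
            error = self._error_model(params)
            om2 = params.get("om_btv", 0.0) ** 2 if self.btv else 0.0
            m2, eta = self._batched_laplace(params, B, refs, om2, error,
                                            eta_state["eta"])
            eta_state["eta"] = eta
            return m2

        result = fit_population(unit_terms, paramset, n_obs=dv.size,
                                compute_se=self.compute_se,
                                maxiter=self.maxiter)
        result.etas = {u["unit_id"]: float(e)
                       for u, e in zip(units, eta_state["eta"])}
        self.result_: FitResult = result
        self.params_ = result.params
        self.refs_ = refs
        self.ofv_ = result.ofv
        self.aic_ = result.aic
        self.se_ = result.se
        self.etas_ = result.etas
        self.converged_ = result.converged
        self.n_obs_ = dv.size
        return self

    def predict(self, X: pd.DataFrame, params: Optional[dict] = None,
                refs: Optional[dict] = None) -> np.ndarray:
        """Typical (eta = 0) released-HPMC predictions, mg."""
        if params is None:
            check_is_fitted(self, "params_")
            params, refs = self.params_, self.refs_
        refs = refs if refs is not None else {**_REFS, "ionic": 0.0}
        X = X.reset_index(drop=True)
        out = np.empty(len(X))
        for u in self._unit_features(X):
            out[u["idx"]] = self._unit_released(params, u, refs)
        return out

    def btv_cv_percent(self) -> float:
        """Fitted between-tablet variability as CV%."""
        check_is_fitted(self, "params_")
        return omega_to_cv_percent(self.params_["om_btv"])

    def minus2ll(self, X: pd.DataFrame, y, params: Optional[dict] = None
                 ) -> float:
        """OFV of data under given (or fitted) population parameters."""
        if params is None:
            check_is_fitted(self, "params_")
            params = self.params_
        refs = getattr(self, "refs_", {**_REFS, "ionic": 0.0})
        X = X.reset_index(drop=True)
        dv = np.asarray(y, dtype=float)
        units = self._unit_features(X)
        error = self._error_model(params)
        om2 = params.get("om_btv", 0.0) ** 2 if self.btv else 0.0
        total = 0.0
        for u in units:
            def pred(e, _u=u):
                return self._unit_released(params, _u, refs, e)
            m2, _ = laplace_scalar_m2ll(pred, dv[u["idx"]], om2, error)
            total += m2
        return total

    def simulate(self, X: pd.DataFrame, rng: np.random.Generator,
                 params: Optional[dict] = None,
                 include_residual: bool = True) -> np.ndarray:
        """One simulated replicate of the dataset design, mg."""
        if params is None:
            check_is_fitted(self, "params_")
            params, refs = self.params_, self.refs_
        else:
            refs = {**_REFS, "ionic": 0.0}
        X = X.reset_index(drop=True)
        error = self._error_model(params)
        om = params.get("om_btv", 0.0) if self.btv else 0.0
        out = np.empty(len(X))
        for u in self._unit_features(X):
            eta = rng.normal(0.0, om) if om > 0 else 0.0
            pred = self._unit_released(params, u, refs, eta)
            if include_residual:
                pred = pred + rng.normal(0.0, error.sd(pred))
            out[u["idx"]] = pred
        return out


# ---------------------------------------------------------------------------
# in vivo estimator


class InVivoErosionModel(BaseEstimator):
    """In vivo erosion model with fixed in vitro structural parameters.

    Estimates the per-segment mechanical stress (USP2 rpm equivalent),
    the in vivo lag time, between-subject and between-occasion
    variability on Vmax and the residual error, using GI-location
    records to build a piecewise-constant environment per occasion.

    Parameters
    ----------
    invitro_params : dict, optional
        In vitro population parameters (typical values and covariate
        coefficients); default are the package's selected-model values.
    segmentation : {"fixed_offset_1h", "fractional_sitt",
        "estimated_offset"}
        Small-intestine proximal/distal segmentation rule applied to
        raw three-region records.
    exclude : sequence of (formulation, prandial)
        Occasions excluded from the estimation OFV (kept for
        diagnostics); defaults to formulation F4 under fasting status.
    """

    def __init__(self, invitro_params: Optional[dict] = None,
                 error: str = "combined",
                 segmentation: str = "fixed_offset_1h",
                 si_offset: float = 1.0,
                 exclude: Sequence[tuple[str, str]] = (("F4", "fasting"),),
                 start: Optional[dict] = None,
                 fixed: Optional[dict] = None,
                 ph_prior: Optional[PhPrior] = None,
                 compute_se: bool = True,
                 maxiter: int = 300,
                 formulations: Optional[dict] = None):
        self.invitro_params = invitro_params
        self.error = error
        self.segmentation = segmentation
        self.si_offset = si_offset
        self.exclude = exclude
        self.start = start
        self.fixed = fixed
        self.ph_prior = ph_prior
        self.compute_se = compute_se
        self.maxiter = maxiter
        self.formulations = formulations

    # -- data preparation -------------------------------------------------

    def _theta(self) -> dict:
        theta = {k: INVITRO_DEFAULTS[k] for k in
                 ("tv_vmax", "tv_km", "s_rpm_vmax", "s_ph_vmax",
                  "s_dcp_vmax", "mk4m50_vmax", "s_ph_km", "s_dcp_km")}
        if self.invitro_params:
            theta.update({k: v for k, v in self.invitro_params.items()
                          if k in theta})
        return theta

    def _build_paramset(self) -> ParamSet:
        start = {k: INVIVO_DEFAULTS[k] for k in
                 ("rpm_stomach", "rpm_proximal_si", "rpm_distal_si",
                  "rpm_colon", "tlag", "om_bsv", "om_bov")}
        start.update({"sigma_add": INVIVO_DEFAULTS["sigma_add"],
                      "sigma_prop": INVIVO_DEFAULTS["sigma_prop"]})
        if self.start:
            start.update(self.start)
        names = ["rpm_stomach", "rpm_proximal_si", "rpm_distal_si",
                 "rpm_colon", "tlag", "om_bsv", "om_bov"]
        if self.error in ("additive", "combined"):
            names.append("sigma_add")
        if self.error in ("proportional", "combined"):
            names.append("sigma_prop")
        params = [Param(n, start[n], "log") for n in names]
        fixed = dict(self.fixed or {})
        for p in params:
            if p.name in fixed:
                p.value = float(fixed[p.name])
                p.fixed = True
        return ParamSet(params)

    def _segments_for(self, gi: pd.DataFrame, subject, occasion,
                      prandial: str) -> list[tuple[float, str, float]]:
        """(entry, segment, pH) triples for one subject-occasion."""
        rows = gi[(gi["subject"] == subject) & (gi["occasion"] == occasion)]
        if rows.empty:
            raise KeyError((subject, occasion))
        segs = list(rows["segment"])
        prior = self.ph_prior or PhPrior()
        if SMALL_INTESTINE in segs:  # raw three-region record
            def entry_of(name):
                sel = rows[rows["segment"] == name]
                return float(sel["entry_time_h"].iloc[0]) if len(sel) else None
            rec = GILocationRecord(
                subject=subject, occasion=occasion, prandial=prandial,
                si_entry=entry_of(SMALL_INTESTINE),
                colon_entry=entry_of(COLON))
            seg_tl = segment_small_intestine(rec, self.segmentation,
                                             self.si_offset)
            return [(t, s, prior.lookup(s, prandial)[0])
                    for s, t in zip(seg_tl.segments, seg_tl.entry_times)]
        out = []
        for _, r in rows.sort_values("entry_time_h").iterrows():
            ph = float(r["ph"]) if "ph" in rows and pd.notna(r.get("ph")) \
                else prior.lookup(r["segment"], prandial)[0]
            out.append((float(r["entry_time_h"]), str(r["segment"]), ph))
        return out

    def _occasion_data(self, X: pd.DataFrame, dv: np.ndarray,
                       gi: pd.DataFrame) -> tuple[list, list]:
        """Group rows into per-subject occasion structures.

        Returns (subjects, excluded) where each subject is a dict with
        occasion entries; excluded occasions are kept separately for
        diagnostics.
        """
        registry = self.formulations or FORMULATIONS
        theta = self._theta()
        excl = {(str(f), str(p)) for f, p in (self.exclude or ())}
        subjects: dict = {}
        excluded: list = []
        for (subj, occ), grp in X.groupby(["subject", "occasion"],
                                          sort=True):
            form = _as_formulation(grp["formulation"].iloc[0], registry)
            prandial = str(grp["prandial"].iloc[0])
            try:
                segs = self._segments_for(gi, subj, occ, prandial)
            except KeyError:
                import warnings
                warnings.warn(f"no GI record for subject {subj} occasion "
                              f"{occ}; occasion dropped", RuntimeWarning)
                continue
            e_dcp_v = max(1.0 + theta["s_dcp_vmax"] * (form.dcp_frac
                                                       - REF_DCP),
                          _MULT_FLOOR)
            e_mk4m = 1.0 - form.mk4m_frac / (theta["mk4m50_vmax"]
                                             + form.mk4m_frac)
            e_dcp_km = max(1.0 + theta["s_dcp_km"] * (form.dcp_frac
                                                      - REF_DCP),
                           _MULT_FLOOR)
            entries, segnames, vmax_base, kms = [], [], [], []
            for entry, name, ph in segs:
                e_ph_v = max(1.0 + theta["s_ph_vmax"] * (ph - REF_PH),
                             _MULT_FLOOR)
                e_ph_km = max(1.0 + theta["s_ph_km"] * (ph - REF_PH),
                              _MULT_FLOOR)
                entries.append(entry)
                segnames.append(name)
                vmax_base.append(theta["tv_vmax"] * e_ph_v * e_dcp_v
                                 * e_mk4m)
                kms.append(max(theta["tv_km"] * e_ph_km * e_dcp_km, 1e-9))
            occ_data = {
                "subject": subj, "occasion": occ, "prandial": prandial,
                "formulation": form, "idx": grp.index.to_numpy(),
                "times": grp["time_h"].to_numpy(dtype=float),
                "dv": dv[grp.index.to_numpy()],
                "entries": np.asarray(entries),
                "segnames": segnames,
                "vmax_base": np.asarray(vmax_base),
                "kms": np.asarray(kms),
                "dose": form.hpmc_dose,
            }
            if (form.name, prandial) in excl:
                excluded.append(occ_data)
            else:
                subjects.setdefault(subj, []).append(occ_data)
        return [{"subject": s, "occasions": occs}
                for s, occs in subjects.items()], excluded

    @staticmethod
    def _seg_rpm(params: dict, name: str) -> float:
        return params[{STOMACH: "rpm_stomach",
                       PROXIMAL_SI: "rpm_proximal_si",
                       DISTAL_SI: "rpm_distal_si",
                       COLON: "rpm_colon"}[name]]

    def _occ_released(self, params: dict, occ: dict, theta: dict,
                      eta: float) -> np.ndarray:
        e_rpm = np.array([max(1.0 + theta["s_rpm_vmax"]
                              * (self._seg_rpm(params, n) - REF_RPM),
                              _MULT_FLOOR) for n in occ["segnames"]])
        vmaxs = occ["vmax_base"] * e_rpm * np.exp(eta)
        return _mm_released_chained(occ["times"], occ["entries"], vmaxs,
                                    occ["kms"], occ["dose"], params["tlag"])

    def _error_model(self, params: dict) -> ErrorModel:
        return ErrorModel(self.error,
                          sigma_add=params.get("sigma_add", 0.0),
                          sigma_prop=params.get("sigma_prop", 0.0))

    # -- batched likelihood (all subjects/occasions at once) --------------

    _SEG_PARAM = ("rpm_stomach", "rpm_proximal_si", "rpm_distal_si",
                  "rpm_colon")
    _SEG_INDEX = {STOMACH: 0, PROXIMAL_SI: 1, DISTAL_SI: 2, COLON: 3}

    def _batched_occasions(self, subjects: list) -> dict:
        occs = [occ for s in subjects for occ in s["occasions"]]
        subj_idx = np.array([i for i, s in enumerate(subjects)
                             for _ in s["occasions"]], dtype=int)
        n_occ = len(occs)
        n_subj = len(subjects)
        t_max = max(o["times"].size for o in occs)
        s_max = max(o["entries"].size for o in occs)
        T = np.zeros((n_occ, t_max))
        DV = np.zeros((n_occ, t_max))
        M = np.zeros((n_occ, t_max), dtype=bool)
        ENT = np.full((n_occ, s_max), np.inf)
        VB = np.zeros((n_occ, s_max))
        KM = np.ones((n_occ, s_max))
        RPI = np.zeros((n_occ, s_max), dtype=int)
        for i, o in enumerate(occs):
            k = o["times"].size
            T[i, :k] = o["times"]
            DV[i, :k] = o["dv"]
            M[i, :k] = True
            ns = o["entries"].size
            ENT[i, :ns] = o["entries"]
            VB[i, :ns] = o["vmax_base"]
            KM[i, :ns] = o["kms"]
            RPI[i, :ns] = [self._SEG_INDEX[n] for n in o["segnames"]]
        return {"subj_idx": subj_idx, "n_occ": n_occ, "n_subj": n_subj,
                "T": T, "DV": DV, "M": M, "ENT": ENT, "VB": VB, "KM": KM,
                "RPI": RPI, "dose": np.array([o["dose"] for o in occs]),
                "J": np.bincount(subj_idx, minlength=n_subj)}

    def _batched_occ_released(self, params: dict, BO: dict,
                              eta_u: np.ndarray) -> np.ndarray:
        """Chained-segment release for every occasion at once."""
        theta = self._theta_cache
        e_seg = np.array([max(1.0 + theta["s_rpm_vmax"]
                              * (params[nm] - REF_RPM), _MULT_FLOOR)
                          for nm in self._SEG_PARAM])
        vmaxs = BO["VB"] * e_seg[BO["RPI"]] * np.exp(eta_u)[:, None]
        tlag = params["tlag"]
        T, ENT, KM = BO["T"], BO["ENT"], BO["KM"]
        dose = BO["dose"]
        n_occ, s_max = ENT.shape
        rel = np.zeros_like(T)
        h = dose.copy()
        a = np.maximum(ENT[:, 0], tlag)
        with np.errstate(divide="ignore", invalid="ignore",
                         over="ignore"):
            for si in range(s_max):
                b = ENT[:, si + 1] if si + 1 < s_max \
                    else np.full(n_occ, np.inf)
                km_s = KM[:, si]
                vm_s = vmaxs[:, si]
                sel = (T > a[:, None]) & (T <= b[:, None]) & BO["M"]
                if np.any(sel):
                    log_x = (np.log(h / km_s)[:, None]
                             + (h[:, None] - vm_s[:, None]
                                * (T - a[:, None])) / km_s[:, None])
                    w = _lambertw_of_exp(np.where(sel, log_x, 0.0))
                    rel = np.where(sel, dose[:, None]
                                   - km_s[:, None] * w, rel)
                upd = np.isfinite(b) & (b > a)
                if np.any(upd):
                    log_xb = np.log(h / km_s) + (h - vm_s * (b - a)) / km_s
                    hn = km_s * _lambertw_of_exp(np.where(upd, log_xb, 0.0))
                    h = np.where(upd, np.maximum(hn, 1e-300), h)
                a = np.where(np.isfinite(b), np.maximum(b, tlag), np.inf)
        return np.clip(np.nan_to_num(rel, nan=0.0), 0.0, dose[:, None])

    def _nested_laplace_batched(self, params: dict, BO: dict,
                                om2_bsv: float, om2_bov: float,
                                error: ErrorModel,
                                state: dict) -> np.ndarray:
        """Per-subject -2 log marginal likelihood, vectorized Newton on
        the arrow-structured inner problem (subject + occasion etas)."""
        subj_idx, S, N = BO["subj_idx"], BO["n_subj"], BO["n_occ"]
        DV, M = BO["DV"], BO["M"]
        J = BO["J"]

        def cll(u: np.ndarray) -> np.ndarray:
            pred = self._batched_occ_released(params, BO, u)
            var = error.variance(pred)
            res = DV - pred
            return np.sum(np.where(M, np.log(2.0 * np.pi * var)
                                   + res * res / var, 0.0), axis=1)

        const = (np.log(2.0 * np.pi * om2_bsv)
                 + J * np.log(2.0 * np.pi * om2_bov))

        def gtot(s: np.ndarray, o: np.ndarray) -> np.ndarray:
            c = cll(s[subj_idx] + o)
            return (np.bincount(subj_idx, c, S) + s * s / om2_bsv
                    + np.bincount(subj_idx, o * o, S) / om2_bov + const)

        s = state["s"].copy()
        o = state["o"].copy()
        g_cur = gtot(s, o)
        om = float(np.sqrt(max(om2_bsv, om2_bov)))
        h = max(1e-2 * om, 1e-4)
        for _ in range(50):
            u = s[subj_idx] + o
            c0, cp, cm = cll(u), cll(u + h), cll(u - h)
            c1 = (cp - cm) / (2.0 * h)
            c2 = np.maximum((cp + cm - 2.0 * c0) / (h * h), 1e-8)
            grad_s = np.bincount(subj_idx, c1, S) + 2.0 * s / om2_bsv
            grad_o = c1 + 2.0 * o / om2_bov
            d = c2 + 2.0 / om2_bov
            A = np.bincount(subj_idx, c2, S) + 2.0 / om2_bsv
            schur = np.maximum(A - np.bincount(subj_idx, c2 * c2 / d, S),
                               1e-8)
            ds = -(grad_s - np.bincount(subj_idx, c2 * grad_o / d, S)) \
                / schur
            do = -(grad_o + c2 * ds[subj_idx]) / d
            gmax = np.maximum(np.abs(grad_s),
                              np.bincount(subj_idx, np.abs(grad_o), S))
            smax = np.maximum(np.abs(ds),
                              np.bincount(subj_idx, np.abs(do), S))
            # expected OFV decrease of the Newton step, per subject
            dec = -0.5 * (grad_s * ds
                          + np.bincount(subj_idx, grad_o * do, S))
            conv = (gmax < 1e-5) | (smax < 1e-6 * om) | (np.abs(dec)
                                                         < 1e-9)
            if np.all(conv):
                break
            ds = np.where(conv, 0.0, ds)
            do = np.where(conv[subj_idx], 0.0, do)
            t_step = np.ones(S)
            for _bt in range(15):
                sn = s + t_step * ds
                on = o + t_step[subj_idx] * do
                gn = gtot(sn, on)
                bad = (gn > g_cur) & ~conv
                if not np.any(bad):
                    break
                t_step = np.where(bad, 0.5 * t_step, t_step)
            ok = gn <= g_cur
            moved = ok & ~conv
            s = np.where(ok, sn, s)
            o = np.where(ok[subj_idx], on, o)
            g_cur = np.where(ok, gn, g_cur)
            if not np.any(moved):
                break  # stalled at numerical precision
        state["s"], state["o"] = s, o

        u = s[subj_idx] + o
        c0, cp, cm = cll(u), cll(u + h), cll(u - h)
        c2 = np.maximum((cp + cm - 2.0 * c0) / (h * h), 1e-8)
        d = c2 + 2.0 / om2_bov
        A = np.bincount(subj_idx, c2, S) + 2.0 / om2_bsv
        schur = np.maximum(A - np.bincount(subj_idx, c2 * c2 / d, S), 1e-10)
        logdet = np.bincount(subj_idx, np.log(d), S) + np.log(schur)
        k = J + 1.0
        return (g_cur - k * np.log(2.0 * np.pi) + logdet
                - k * np.log(2.0))

    # -- estimator API ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y, gi_records: pd.DataFrame
            ) -> "InVivoErosionModel":
        X = X.reset_index(drop=True)
        dv = np.asarray(y, dtype=float)
        if dv.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        theta = self._theta()
        self._theta_cache = theta
        subjects, excluded = self._occasion_data(X, dv, gi_records)
        paramset = self._build_paramset()
        BO = self._batched_occasions(subjects)
        state = {"s": np.zeros(BO["n_subj"]), "o": np.zeros(BO["n_occ"])}
        n_obs = int(sum(occ["times"].size for s in subjects
                        for occ in s["occasions"]))

        def unit_terms(x: np.ndarray) -> np.ndarray:
            params = paramset.unpack(x)
            error = self._error_model(params)
            om2_bsv = params["om_bsv"] ** 2
            om2_bov = params["om_bov"] ** 2
            if om2_bsv <= 0.0 or om2_bov <= 0.0:
                # degenerate variances: per-subject generic path
                out = np.empty(len(subjects))
                for i, s in enumerate(subjects):
                    fns = [lambda e, _o=occ, _p=params: self._occ_released(
                        _p, _o, theta, e) for occ in s["occasions"]]
                    dvs = [occ["dv"] for occ in s["occasions"]]
                    m2, _ = laplace_nested_m2ll(fns, dvs, om2_bsv,
                                                om2_bov, error)
                    out[i] = m2
                return out
            return self._nested_laplace_batched(params, BO, om2_bsv,
                                                om2_bov, error, state)

        result = fit_population(unit_terms, paramset, n_obs=n_obs,
                                compute_se=self.compute_se,
                                maxiter=self.maxiter)
        result.etas = {
            s["subject"]: np.concatenate(
                [[state["s"][i]],
                 state["o"][BO["subj_idx"] == i]])
            for i, s in enumerate(subjects)}
        self.result_ = result
        self.params_ = result.params
        self.theta_ = theta
        self.se_ = result.se
        self.ofv_ = result.ofv
        self.aic_ = result.aic
        self.converged_ = result.converged
        self.subjects_ = subjects
        self.excluded_ = excluded
        self.n_obs_ = n_obs
        return self

    def rpm_params(self) -> RpmParams:
        check_is_fitted(self, "params_")
        return RpmParams(self.params_["rpm_stomach"],
                         self.params_["rpm_proximal_si"],
                         self.params_["rpm_distal_si"],
                         self.params_["rpm_colon"])

    def bsv_cv_percent(self) -> float:
        check_is_fitted(self, "params_")
        return omega_to_cv_percent(self.params_["om_bsv"])

    def bov_cv_percent(self) -> float:
        check_is_fitted(self, "params_")
        return omega_to_cv_percent(self.params_["om_bov"])

    def _prediction_subjects(self, X: pd.DataFrame,
                             gi_records: pd.DataFrame,
                             ph_mode: str) -> list:
        """Occasion structures for prediction/simulation (no exclusion),
        cached per (X, gi, ph_mode) identity for repeated use on a fixed
        design (e.g. VPC replicates)."""
        cache = getattr(self, "_design_cache", None)
        if cache is None:
            cache = self._design_cache = {}
        key = (id(X), id(gi_records), ph_mode, len(X))
        if key in cache:
            return cache[key]
        gi = gi_records
        if ph_mode == "deterministic" and "ph" in gi.columns:
            gi = gi.drop(columns=["ph"])
        saved_exclude = self.exclude
        try:
            self.exclude = ()
            subjects, _ = self._occasion_data(
                X.reset_index(drop=True), np.zeros(len(X)), gi)
        finally:
            self.exclude = saved_exclude
        if len(cache) > 8:
            cache.pop(next(iter(cache)))
        cache[key] = subjects
        return subjects

    def predict(self, X: pd.DataFrame, gi_records: pd.DataFrame,
                params: Optional[dict] = None,
                ph_mode: str = "deterministic") -> np.ndarray:
        """Typical predictions (eta = 0), deterministic prior-mean pH by
        default (set ``ph_mode='recorded'`` to use recorded draws)."""
        if params is None:
            check_is_fitted(self, "params_")
            params = self.params_
        theta = self._theta()
        subjects = self._prediction_subjects(X, gi_records, ph_mode)
        out = np.full(len(X), np.nan)
        for s in subjects:
            for occ in s["occasions"]:
                out[occ["idx"]] = self._occ_released(params, occ, theta, 0.0)
        return out

    def simulate(self, X: pd.DataFrame, gi_records: pd.DataFrame,
                 rng: np.random.Generator,
                 params: Optional[dict] = None,
                 ph_mode: str = "recorded",
                 include_residual: bool = True) -> np.ndarray:
        """One replicate under the model: new subject/occasion random
        effects and residual noise on the dataset's design."""
        if params is None:
            check_is_fitted(self, "params_")
            params = self.params_
        theta = self._theta()
        subjects = self._prediction_subjects(X, gi_records, ph_mode)
        error = self._error_model(params)
        out = np.full(len(X), np.nan)
        for s in subjects:
            eta_s = rng.normal(0.0, params["om_bsv"])
            for occ in s["occasions"]:
                eta = eta_s + rng.normal(0.0, params["om_bov"])
                pred = self._occ_released(params, occ, theta, eta)
                if include_residual:
                    pred = pred + rng.normal(0.0, error.sd(pred))
                out[occ["idx"]] = pred
        return out


# ---------------------------------------------------------------------------
# stepwise covariate modeling


@dataclass
class ScmStep:
    action: str  # "add" | "upgrade" | "remove"
    relation: Relation
    delta_ofv: float
    p_value: float
    accepted: bool


@dataclass
class ScmResult:
    relations: tuple[Relation, ...]
    path: list[ScmStep]
    final_model: InVitroErosionModel
    forward_threshold: float
    backward_threshold: float


DEFAULT_CANDIDATES: tuple[Relation, ...] = tuple(
    Relation(cov, target, "linear")
    for cov in ("rpm", "ph", "ionic", "dcp", "mk4m")
    for target in ("vmax", "km"))


class StepwiseCovariateSelector(BaseEstimator):
    """Forward-inclusion / backward-deletion covariate selection.

    Linear relations are tested first; power and saturable (Emax)
    upgrades of an included linear relation are only evaluated for
    covariates observed over a wide range (``upgrade_covs``).  Forward
    inclusion requires p < ``forward_alpha`` on a likelihood-ratio
    chi-square; retained relations must survive backward deletion at
    the stricter ``backward_alpha``.
    """

    def __init__(self, candidates: Sequence[Relation] = DEFAULT_CANDIDATES,
                 base_relations: Sequence[Relation] = (),
                 forward_alpha: float = 0.05,
                 backward_alpha: float = 0.01,
                 upgrade_covs: Sequence[str] = ("rpm", "mk4m"),
                 structural: str = "michaelis-menten",
                 error: str = "additive", btv: bool = True,
                 start: Optional[dict] = None,
                 maxiter: int = 200,
                 try_upgrades: bool = True,
                 max_steps: Optional[int] = None):
        self.candidates = candidates
        self.base_relations = base_relations
        self.forward_alpha = forward_alpha
        self.backward_alpha = backward_alpha
        self.upgrade_covs = upgrade_covs
        self.structural = structural
        self.error = error
        self.btv = btv
        self.start = start
        self.maxiter = maxiter
        self.try_upgrades = try_upgrades
        self.max_steps = max_steps

    def _fit_model(self, X, y, relations: tuple[Relation, ...],
                   warm: Optional[dict] = None) -> InVitroErosionModel:
        start = dict(self.start or {})
        if warm is not None:  # warm-start nested fits from the incumbent
            start.update(warm)
        m = InVitroErosionModel(structural=self.structural,
                                relations=relations, error=self.error,
                                btv=self.btv, start=start,
                                compute_se=False, maxiter=self.maxiter)
        return m.fit(X, y)

    def fit(self, X: pd.DataFrame, y) -> "StepwiseCovariateSelector":
        path: list[ScmStep] = []
        current = tuple(self.base_relations)
        model = self._fit_model(X, y, current)
        n_steps = 0

        # forward inclusion
        while self.max_steps is None or n_steps < self.max_steps:
            cands: list[tuple[Relation, Optional[Relation], int]] = []
            for c in self.candidates:
                if c.form != "linear":
                    continue
                if any(r.cov == c.cov and r.target == c.target
                       for r in current):
                    continue
                cands.append((c, None, 1))
            if self.try_upgrades:
                for r in current:
                    if r.form == "linear" and r.cov in self.upgrade_covs:
                        for form in ("power", "emax"):
                            cands.append((Relation(r.cov, r.target, form),
                                          r, 1))
            if not cands:
                break
            warm = dict(model.params_)
            best = None
            for cand, replaces, df in cands:
                new = tuple(r for r in current if r is not replaces) + (cand,)
                m = self._fit_model(X, y, new, warm=warm)
                d_ofv = model.ofv_ - m.ofv_
                p = float(chi2.sf(max(d_ofv, 0.0), df))
                if p < self.forward_alpha and (
                        best is None or d_ofv > best[2]):
                    best = (cand, new, d_ofv, p, m, replaces)
            if best is None:
                break
            cand, new, d_ofv, p, m, replaces = best
            path.append(ScmStep("upgrade" if replaces else "add",
                                cand, d_ofv, p, True))
            current, model = new, m
            n_steps += 1

        # backward deletion
        while True:
            worst = None
            warm = dict(model.params_)
            for r in current:
                reduced = tuple(x for x in current if x is not r)
                m = self._fit_model(X, y, reduced, warm=warm)
                d_ofv = m.ofv_ - model.ofv_
                p = float(chi2.sf(max(d_ofv, 0.0), r.n_params))
                if p >= self.backward_alpha and (
                        worst is None or d_ofv < worst[2]):
                    worst = (r, reduced, d_ofv, p, m)
            if worst is None:
                break
            r, reduced, d_ofv, p, m = worst
            path.append(ScmStep("remove", r, d_ofv, p, True))
            current, model = reduced, m

        self.relations_ = current
        self.path_ = path
        self.final_model_ = model
        self.result_ = ScmResult(
            relations=current, path=path, final_model=model,
            forward_threshold=float(chi2.ppf(1 - self.forward_alpha, 1)),
            backward_threshold=float(chi2.ppf(1 - self.backward_alpha, 1)))
        return self


def scm(X: pd.DataFrame, y, **kwargs) -> ScmResult:
    """Functional wrapper around :class:`StepwiseCovariateSelector`."""
    return StepwiseCovariateSelector(**kwargs).fit(X, y).result_
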