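"""Covariate model linking formulation and environment to Vmax and Km.

Covariate effects enter multiplicatively on the typical parameter
values, each centered at the reference condition (formulation F3, pH
6.8, 50 rpm mechanical stress, 57.6 %w/w DCP):

* linear:  ``1 + S * (cov - ref)``
* power:   ``(cov / ref) ** PWR``
* emax:    ``1 + Emax * cov / (cov50 + cov)``

The selected model uses linear pH, mechanical-stress (rpm) and DCP
effects on Vmax, a saturable inhibitory effect of the high molecular
weight HPMC share (Emax fixed at -1, i.e. full inhibition at infinite
MK4M), and linear pH and DCP effects on Km.  Multipliers are floored at
a small positive value so that rates stay positive at extreme
covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .formulations import Formulation

import numpy as np

#: Reference (centering) covariate values: the typical condition.
REF_RPM = 50.0
REF_PH = 6.8
REF_DCP = 57.6

_MULT_FLOOR = 1e-6


@dataclass(frozen=True)
class CovariateParams:
    """Typical values and covariate-effect coefficients.

    Defaults are the selected in vitro model estimates: typical Vmax
    22.0 mg/h and Km 34.2 mg at the reference condition, linear slopes
    per covariate unit, and the MK4M content halving Vmax at
    18.7 %w/w.
    """

    tv_vmax: float = 22.0
    tv_km: float = 34.2
    s_rpm_vmax: float = 0.0115
    s_ph_vmax: float = -0.0319
    s_dcp_vmax: float = 0.0332
    s_ph_km: float = 0.0935
    s_dcp_km: float = 0.0522
    mk4m50_vmax: float = 18.7
    emax_mk4m: float = -1.0

    def __post_init__(self) -> None:
        if self.tv_vmax <= 0 or self.tv_km <= 0 or self.mk4m50_vmax <= 0:
            raise ValueError("typical values and MK4M50 must be positive")
        if not -1.0 <= self.emax_mk4m <= 0.0:
            raise ValueError("emax_mk4m must lie in [-1, 0]")


def covariate_effect(cov: float, ref: float, form: str, **coeffs) -> float:
    """Dimensionless multiplier for one covariate-parameter relation.

    ``form`` is one of ``linear`` (coeff ``slope``), ``power``
    (coeff ``pwr``) or ``emax`` (coeffs ``emax``, ``cov50``).
    """
    if form == "linear":
        mult = 1.0 + coeffs["slope"] * (cov - ref)
    elif form == "power":
        if ref <= 0 or cov <= 0:
            raise ValueError("power form needs positive covariate and ref")
        mult = (cov / ref) ** coeffs["pwr"]
    elif form == "emax":
        if cov < 0:
            raise ValueError("emax form needs non-negative covariate")
        mult = 1.0 + coeffs["emax"] * cov / (coeffs["cov50"] + cov)
    else:
        raise ValueError(f"unknown covariate-effect form {form!r}")
    return _floor(mult)


def _floor(mult: float) -> float:
    if mult <= _MULT_FLOOR:
        warnings.warn("covariate multiplier clipped at positive floor",
                      RuntimeWarning, stacklevel=3)
        return _MULT_FLOOR
    return float(mult)


def emk4m_effect(mk4m: float, mk4m50: float) -> float:
    """Saturable inhibition of Vmax by high molecular weight HPMC.

    ``1 - MK4M / (MK4M50 + MK4M)``, in (0, 1]; equals 1 for
    formulations without Methocel K4M and 0.5 at ``mk4m = mk4m50``.
    """
    if mk4m < 0 or mk4m50 <= 0:
        raise ValueError("mk4m must be >= 0 and mk4m50 > 0")
    return 1.0 - mk4m / (mk4m50 + mk4m)


def vmax_from_covariates(cp: CovariateParams, formulation: Formulation,
                         ph: float, rpm: float, eta: float = 0.0) -> float:
    """Individual Vmax (mg/h) from the multiplicative covariate model.

    ``Vmax = TV * E_rpm * E_pH * E_DCP * E_MK4M * exp(eta)`` with
    ``eta`` a log-scale random effect.
    """
    e_rpm = covariate_effect(rpm, REF_RPM, "linear", slope=cp.s_rpm_vmax)
    e_ph = covariate_effect(ph, REF_PH, "linear", slope=cp.s_ph_vmax)
    e_dcp = covariate_effect(formulation.dcp_frac, REF_DCP, "linear",
                             slope=cp.s_dcp_vmax)
    e_mk4m = emk4m_effect(formulation.mk4m_frac, cp.mk4m50_vmax) \
        if cp.emax_mk4m == -1.0 else covariate_effect(
            formulation.mk4m_frac, 0.0, "emax",
            emax=cp.emax_mk4m, cov50=cp.mk4m50_vmax)
    return cp.tv_vmax * e_rpm * e_ph * e_dcp * e_mk4m * float(np.exp(eta))


def km_from_covariates(cp: CovariateParams, formulation: Formulation,
                       ph: float) -> float:
    """Individual Km (mg): ``TV * E_pH * E_DCP``."""
    e_ph = covariate_effect(ph, REF_PH, "linear", slope=cp.s_ph_km)
    e_dcp = covariate_effect(formulation.dcp_frac, REF_DCP, "linear",
                             slope=cp.s_dcp_km)
    return cp.tv_km * e_ph * e_dcp
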