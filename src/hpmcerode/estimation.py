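"""Nonlinear mixed-effects estimation by Laplace approximation.

The marginal likelihood of each grouping unit (a tablet in vitro; a
subject with nested occasions in vivo) is approximated by the Laplace
method with interaction: the random-effect vector ``eta`` is optimized
per unit (empirical Bayes mode) and the Gaussian integral is corrected
with the log-determinant of the joint negative log-density curvature.
The residual variance may depend on ``eta`` through the predictions
(interaction), as in FOCE-I.

Random effects are log-normal on the target parameter: predictions are
evaluated at ``exp(eta)`` times the typical value.  Two grouping
layouts are supported:

* independent units, one scalar ``eta`` each (between-tablet
  variability);
* subjects with occasions, where occasion ``j`` of a subject sees
  ``eta_subject + eta_occasion_j`` (between-subject plus
  between-occasion variability), giving an arrow-structured inner
  Hessian that is exploited in the Newton solve and the determinant.

Outer (population) parameters are estimated by quasi-Newton
minimization of the summed -2 log marginal likelihood (OFV) with
positivity enforced through log-transforms; uncertainty comes from a
sandwich estimator (per-unit score outer products between inverse
Hessians).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class ErrorModel:
    """Residual unexplained variability model.

    ``additive`` has constant SD ``sigma_add`` (mg); ``proportional``
    has SD proportional to the prediction (``sigma_prop`` as CV
    fraction); ``combined`` adds both variances.
    """

    family: str = "additive"
    sigma_add: float = 1.95
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error family {self.family!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("error SDs must be non-negative")
        if self.effective_sigmas() == (0.0, 0.0):
            raise ValueError("at least one error SD must be positive")

    def effective_sigmas(self) -> tuple[float, float]:
        add = self.sigma_add if self.family in ("additive", "combined") else 0.0
        prop = self.sigma_prop if self.family in ("proportional",
                                                  "combined") else 0.0
        return add, prop

    def variance(self, pred: np.ndarray) -> np.ndarray:
        add, prop = self.effective_sigmas()
        return np.maximum(add ** 2 + (prop * pred) ** 2, _VAR_FLOOR)

    def sd(self, pred: np.ndarray) -> np.ndarray:
        return np.sqrt(self.variance(pred))


def conditional_minus2ll(dv: np.ndarray, pred: np.ndarray,
                         error: ErrorModel) -> float:
    """-2 log-likelihood of observations given predictions (Gaussian)."""
    pred = np.asarray(pred, dtype=float)
    if not np.all(np.isfinite(pred)):
        return float("inf")
    var = error.variance(pred)
    res = np.asarray(dv, dtype=float) - pred
    return float(np.sum(np.log(2.0 * np.pi * var) + res * res / var))


# ---------------------------------------------------------------------------
# inner (empirical Bayes) optimization


def _minimize_1d(g: Callable[[float], float], x0: float, scale: float,
                 max_iter: int = 40, tol: float = 1e-7) -> tuple[float, float]:
    """Damped finite-difference Newton minimization of a smooth 1-D
    function; returns (argmin, min)."""
    h = max(1e-2 * scale, 1e-4)
    x, gx = x0, g(x0)
    if not np.isfinite(gx):
        x, gx = 0.0, g(0.0)
    for _ in range(max_iter):
        gp, gm = g(x + h), g(x - h)
        d1 = (gp - gm) / (2.0 * h)
        d2 = (gp + gm - 2.0 * gx) / (h * h)
        if d2 >= 0.0 and (abs(d1) < max(tol * abs(gx), 1e-4)
                          or (d2 > 1e-12
                              and abs(d1 / d2) < 1e-5 * scale)):
            break
        step = -d1 / d2 if d2 > 1e-12 else -np.sign(d1) * scale
        step = float(np.clip(step, -5.0 * scale, 5.0 * scale))
        xn, gn = x + step, g(x + step)
        n_back = 0
        while gn > gx and n_back < 25:
            step *= 0.5
            xn, gn = x + step, g(x + step)
            n_back += 1
        if abs(xn - x) < 1e-10 and n_back == 0:
            x, gx = xn, gn
            break
        if gn <= gx:
            x, gx = xn, gn
    return x, gx


def laplace_scalar_m2ll(pred_fn: Callable[[float], np.ndarray],
                        dv: np.ndarray, omega2: float, error: ErrorModel,
                        eta0: float = 0.0) -> tuple[float, float]:
    """-2 log marginal likelihood of one unit with a scalar random
    effect of variance ``omega2``; returns (m2ll, eta_hat)."""
    if omega2 <= 0.0:
        return conditional_minus2ll(dv, pred_fn(0.0), error), 0.0
    omega = float(np.sqrt(omega2))

    def g(e: float) -> float:
        return (conditional_minus2ll(dv, pred_fn(e), error)
                + e * e / omega2 + _LOG2PI + np.log(omega2))

    eta, g_eta = _minimize_1d(g, eta0, scale=omega)
    h = max(1e-2 * omega, 1e-4)
    curv = (g(eta + h) + g(eta - h) - 2.0 * g_eta) / (h * h)
    curv = max(curv, 2.0 / omega2 * 1e-3)  # guard pathological flatness
    m2ll = g_eta - _LOG2PI + np.log(curv / 2.0)
    return float(m2ll), float(eta)


def laplace_nested_m2ll(
    occ_pred_fns: Sequence[Callable[[float], np.ndarray]],
    occ_dvs: Sequence[np.ndarray],
    om2_bsv: float,
    om2_bov: float,
    error: ErrorModel,
    eta0: Optional[np.ndarray] = None,
    max_iter: int = 60,
) -> tuple[float, np.ndarray]:
    """-2 log marginal likelihood of one subject with nested occasions.

    Occasion ``j`` predictions are evaluated at ``eta_s + eta_oj``;
    returns ``(m2ll, eta_hat)`` with ``eta_hat = [s, o_1, ..., o_J]``.
    Degenerate variance components collapse to the simpler layouts.
    """
    J = len(occ_pred_fns)
    if om2_bsv <= 0.0 and om2_bov <= 0.0:
        m2 = sum(conditional_minus2ll(dv, fn(0.0), error)
                 for fn, dv in zip(occ_pred_fns, occ_dvs))
        return float(m2), np.zeros(J + 1)
    if om2_bsv <= 0.0:
        total, etas = 0.0, [0.0]
        for j, (fn, dv) in enumerate(zip(occ_pred_fns, occ_dvs)):
            e0 = 0.0 if eta0 is None else float(eta0[j + 1])
            m2, e = laplace_scalar_m2ll(fn, dv, om2_bov, error, e0)
            total += m2
            etas.append(e)
        return float(total), np.asarray(etas)
    if om2_bov <= 0.0:
        def pooled(e: float) -> np.ndarray:
            return np.concatenate([fn(e) for fn in occ_pred_fns])
        dv_all = np.concatenate([np.asarray(d, float) for d in occ_dvs])
        e0 = 0.0 if eta0 is None else float(eta0[0])
        m2, e = laplace_scalar_m2ll(pooled, dv_all, om2_bsv, error, e0)
        return m2, np.concatenate([[e], np.zeros(J)])

    def gocc(j: int, u: float) -> float:
        return conditional_minus2ll(occ_dvs[j], occ_pred_fns[j](u), error)

    const = (_LOG2PI + np.log(om2_bsv)) + J * (_LOG2PI + np.log(om2_bov))

    def gtot(s: float, o: np.ndarray) -> float:
        return (sum(gocc(j, s + o[j]) for j in range(J))
                + s * s / om2_bsv + float(np.sum(o * o)) / om2_bov + const)

    s = 0.0 if eta0 is None else float(eta0[0])
    o = np.zeros(J) if eta0 is None else np.asarray(eta0[1:], float).copy()
    g_cur = gtot(s, o)
    if not np.isfinite(g_cur):
        s, o = 0.0, np.zeros(J)
        g_cur = gtot(s, o)
    h = max(1e-2 * float(np.sqrt(max(om2_bsv, om2_bov))), 1e-4)

    for _ in range(max_iter):
        c1 = np.empty(J)
        c2 = np.empty(J)
        for j in range(J):
            u = s + o[j]
            gp, gm = gocc(j, u + h), gocc(j, u - h)
            g0 = gocc(j, u)
            c1[j] = (gp - gm) / (2.0 * h)
            c2[j] = max((gp + gm - 2.0 * g0) / (h * h), 1e-8)
        grad_s = float(np.sum(c1)) + 2.0 * s / om2_bsv
        grad_o = c1 + 2.0 * o / om2_bov
        gnorm = max(abs(grad_s), float(np.max(np.abs(grad_o))))
        if gnorm < 1e-6 * max(1.0, abs(g_cur)):
            break
        # arrow-structured Newton solve (Schur complement on s)
        d = c2 + 2.0 / om2_bov
        a = float(np.sum(c2)) + 2.0 / om2_bsv
        schur = a - float(np.sum(c2 * c2 / d))
        schur = max(schur, 1e-8)
        ds = -(grad_s - float(np.sum(c2 * grad_o / d))) / schur
        do = -(grad_o + c2 * ds) / d
        step = 1.0
        improved = False
        for _bt in range(25):
            sn, on = s + step * ds, o + step * do
            gn = gtot(sn, on)
            if gn <= g_cur:
                s, o, g_cur = sn, on, gn
                improved = True
                break
            step *= 0.5
        if not improved:
            break

    # curvature at the mode for the Laplace determinant
    c2 = np.empty(J)
    for j in range(J):
        u = s + o[j]
        c2[j] = max((gocc(j, u + h) + gocc(j, u - h)
                     - 2.0 * gocc(j, u)) / (h * h), 1e-8)
    d = c2 + 2.0 / om2_bov
    a = float(np.sum(c2)) + 2.0 / om2_bsv
    logdet = float(np.sum(np.log(d))) + np.log(max(a - np.sum(c2 ** 2 / d),
                                                   1e-10))
    k = J + 1
    m2ll = g_cur - k * _LOG2PI + logdet - k * np.log(2.0)
    return float(m2ll), np.concatenate([[s], o])


def foce_minus2ll(unit_pred_fns: Sequence[Callable[[float], np.ndarray]],
                  unit_dvs: Sequence[np.ndarray], omega2: float,
                  error: ErrorModel,
                  etas0: Optional[Sequence[float]] = None) -> float:
    """Objective function value: summed -2 log marginal likelihood of
    independent units with a scalar log-normal random effect.

    The zero-variance limit collapses to the conditional likelihood at
    eta = 0.  Nested (subject/occasion) layouts use
    :func:`laplace_nested_m2ll` directly.
    """
    total = 0.0
    for i, (fn, dv) in enumerate(zip(unit_pred_fns, unit_dvs)):
        e0 = 0.0 if etas0 is None else float(etas0[i])
        m2, _ = laplace_scalar_m2ll(fn, dv, omega2, error, e0)
        total += m2
    return total


# ---------------------------------------------------------------------------
# population parameter handling


@dataclass
class Param:
    """One population parameter: natural value, transform, fixed flag.

    ``scale`` rescales identity-transformed parameters internally so
    the outer optimizer sees O(1) quantities (e.g. covariate slopes of
    magnitude ~0.01 get scale 0.01).
    """

    name: str
    value: float
    transform: str = "log"  # "log" | "identity"
    fixed: bool = False
    scale: float = 1.0

    def to_internal(self) -> float:
        if self.transform == "log":
            if self.value <= 0:
                raise ValueError(f"{self.name}: log-transform needs > 0")
            return float(np.log(self.value))
        return float(self.value) / self.scale

    def from_internal(self, x: float) -> float:
        return float(np.exp(x)) if self.transform == "log" \
            else float(x) * self.scale


class ParamSet:
    """Ordered collection of population parameters with fixed masks."""

    def __init__(self, params: Sequence[Param]):
        self.params = list(params)
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def free(self) -> list[Param]:
        return [p for p in self.params if not p.fixed]

    @property
    def n_free(self) -> int:
        return len(self.free)

    def pack(self) -> np.ndarray:
        return np.array([p.to_internal() for p in self.free])

    def unpack(self, x: np.ndarray) -> dict[str, float]:
        out = {p.name: p.value for p in self.params}
        for p, xi in zip(self.free, x):
            out[p.name] = p.from_internal(float(xi))
        return out

    def natural_jacobian(self, x: np.ndarray) -> np.ndarray:
        """d(natural)/d(internal) for each free parameter at ``x``."""
        return np.array([np.exp(xi) if p.transform == "log" else p.scale
                         for p, xi in zip(self.free, x)])


@dataclass
class FitResult:
    """Outcome of a population fit."""

    params: dict[str, float]
    fixed: dict[str, bool]
    ofv: float
    aic: float
    n_free: int
    n_obs: int
    se: dict[str, float] = field(default_factory=dict)
    etas: dict = field(default_factory=dict)
    converged: bool = True
    log: list[str] = field(default_factory=list)

    def rse_percent(self, name: str) -> float:
        """Relative standard error (%) of an estimated parameter."""
        return 100.0 * self.se[name] / abs(self.params[name])

    def to_dict(self) -> dict:
        return {
            "params": self.params, "fixed": self.fixed, "ofv": self.ofv,
            "aic": self.aic, "n_free": self.n_free, "n_obs": self.n_obs,
            "se": self.se, "converged": self.converged, "log": self.log,
        }


def omega_to_cv_percent(omega: float) -> float:
    """Log-normal SD ``omega`` -> CV% = 100 * sqrt(exp(omega^2) - 1)."""
    return 100.0 * float(np.sqrt(np.expm1(omega ** 2)))


def cv_percent_to_omega(cv: float) -> float:
    """Inverse of :func:`omega_to_cv_percent`."""
    return float(np.sqrt(np.log1p((cv / 100.0) ** 2)))


def fit_population(
    unit_terms: Callable[[np.ndarray], np.ndarray],
    paramset: ParamSet,
    n_obs: int,
    compute_se: bool = True,
    maxiter: int = 300,
    log: Optional[list[str]] = None,
) -> FitResult:
    """Minimize the summed per-unit -2 log marginal likelihood.

    ``unit_terms(x)`` returns the vector of per-unit OFV contributions
    at internal parameter vector ``x``; its sum is the OFV.
    """
    log = [] if log is None else log
    x0 = paramset.pack()

    def f(x: np.ndarray) -> float:
        val = float(np.sum(unit_terms(x)))
        return val if np.isfinite(val) else 1e12

    converged = True
    if paramset.n_free:
        res = minimize(f, x0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-11,
                                "gtol": 1e-6, "eps": 1e-5})
        if not res.success:
            converged = False
            log.append(f"outer optimizer: {res.message}")
        x_hat, ofv = res.x, float(res.fun)
    else:
        x_hat, ofv = x0, f(x0)

    params = paramset.unpack(x_hat)
    se: dict[str, float] = {}
    if compute_se and paramset.n_free:
        se = _sandwich_se(unit_terms, paramset, x_hat, log)
    aic = ofv + 2.0 * paramset.n_free
    return FitResult(params=params,
                     fixed={p.name: p.fixed for p in paramset.params},
                     ofv=ofv, aic=aic, n_free=paramset.n_free, n_obs=n_obs,
                     se=se, converged=converged, log=log)


def _sandwich_se(unit_terms, paramset: ParamSet, x_hat: np.ndarray,
                 log: list[str]) -> dict[str, float]:
    """Sandwich covariance: per-unit score cross-products between
    inverse Hessians of the -2 log-likelihood halves."""
    p = x_hat.size
    hs = 1e-4 * np.maximum(np.abs(x_hat), 1.0)
    base = np.asarray(unit_terms(x_hat), dtype=float)
    n_units = base.size

    grads = np.empty((n_units, p))
    plus_cache, minus_cache = [], []
    for i in range(p):
        xp, xm = x_hat.copy(), x_hat.copy()
        xp[i] += hs[i]
        xm[i] -= hs[i]
        tp, tm = np.asarray(unit_terms(xp)), np.asarray(unit_terms(xm))
        plus_cache.append(tp)
        minus_cache.append(tm)
        grads[:, i] = (tp - tm) / (2.0 * hs[i])

    H = np.empty((p, p))
    for i in range(p):
        H[i, i] = float(np.sum(plus_cache[i]) + np.sum(minus_cache[i])
                        - 2.0 * np.sum(base)) / hs[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x_hat.copy(); xpp[[i, j]] += hs[[i, j]]
            xmm = x_hat.copy(); xmm[[i, j]] -= hs[[i, j]]
            fpp, fmm = np.sum(unit_terms(xpp)), np.sum(unit_terms(xmm))
            fpi = np.sum(plus_cache[i]); fpj = np.sum(plus_cache[j])
            fmi = np.sum(minus_cache[i]); fmj = np.sum(minus_cache[j])
            f0 = np.sum(base)
            H[i, j] = H[j, i] = float(
                fpp - fpi - fpj + 2.0 * f0 - fmi - fmj + fmm
            ) / (2.0 * hs[i] * hs[j])

    A = H / 2.0  # observed information of the log-likelihood
    B = 0.25 * grads.T @ grads  # score outer products
    try:
        Ainv = np.linalg.inv(A)
        cov = Ainv @ B @ Ainv
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("non-positive sandwich variance")
    except np.linalg.LinAlgError:
        log.append("sandwich covariance singular; falling back to "
                   "Hessian-only standard errors")
        try:
            cov = np.linalg.pinv(A)
        except np.linalg.LinAlgError:
            return {}
    jac = paramset.natural_jacobian(x_hat)
    var = np.clip(np.diag(cov), 0.0, None)
    return {prm.name: float(np.sqrt(v) * abs(j))
            for prm, v, j in zip(paramset.free, var, jac)}
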