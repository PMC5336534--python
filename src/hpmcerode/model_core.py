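"""Structural tablet-erosion models.

Erosion is tracked as the amount of HPMC remaining in the tablet,
``H(t)`` (mg), starting at the HPMC dose.  Two rate laws are supported:

* Michaelis-Menten depletion, ``dH/dt = -Vmax * H / (Km + H)``, where
  ``Vmax`` (mg/h) is the maximal release rate and ``Km`` (mg) the
  remaining amount at which the rate is half-maximal.  Over an interval
  with constant parameters this ODE has a closed-form solution in terms
  of the principal branch of the Lambert W function, which is the
  default solver; an adaptive Runge-Kutta fallback is kept as an
  independent numerical route.
* A mechanism-based surface-area law,
  ``dH/dt = -R * (dose/W) * (W * H / dose)**gamma``, with basal rate
  ``R`` (1/h), power ``gamma`` and tablet weight ``W`` (mg).

Release starts after a lag time attributed to initial tablet hydration:
no state change occurs before ``tlag`` and the release clock starts
there.  Time-varying environments (e.g. pH changing on gastric
emptying) enter through a piecewise-constant parameter timeline; the
state is propagated continuously across segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import lambertw


class TimelineError(ValueError):
    """Raised when a parameter timeline does not cover the request."""


@dataclass(frozen=True)
class StructuralParams:
    """Structural parameters shared by both rate laws.

    ``vmax``/``km`` drive the Michaelis-Menten law, ``r_basal``/``gamma``
    the mechanism-based law; ``tlag`` (h) delays release onset.
    """

    vmax: float = 22.0
    km: float = 34.2
    tlag: float = 0.179
    r_basal: float = 0.15
    gamma: float = 0.8

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0 or self.r_basal <= 0:
            raise ValueError("vmax, km and r_basal must be positive")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass(frozen=True)
class ReleaseState:
    """State of one tablet at one time: remaining and released HPMC (mg)."""

    time: float
    hpmc_tablet: float
    released: float


@dataclass
class ParamTimeline:
    """Piecewise-constant (vmax, km) over time.

    ``breakpoints`` are the left edges of the intervals (the first must
    be 0); interval ``i`` spans ``[breakpoints[i], breakpoints[i+1])``
    and the last extends to infinity.  Used to carry time-varying
    covariate effects into the ODE solution.
    """

    breakpoints: Sequence[float] = field(default_factory=lambda: [0.0])
    segment_params: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(22.0, 34.2)])

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        if bp.size == 0 or bp[0] != 0.0:
            raise TimelineError("timeline must start at t = 0")
        if np.any(np.diff(bp) <= 0):
            raise TimelineError("breakpoints must be strictly increasing")
        if len(self.segment_params) != bp.size:
            raise TimelineError(
                "need exactly one (vmax, km) pair per breakpoint")

    @classmethod
    def constant(cls, vmax: float, km: float) -> "ParamTimeline":
        return cls([0.0], [(vmax, km)])


def michaelis_menten_rate(h_tablet, vmax: float, km: float):
    """Release-rate magnitude vmax * H / (Km + H) in mg/h."""
    h = np.asarray(h_tablet, dtype=float)
    if np.any(h < 0):
        raise ValueError("remaining HPMC must be non-negative")
    if vmax < 0 or km < 0:
        raise ValueError("vmax and km must be non-negative")
    out = vmax * h / (km + h)
    return out if out.ndim else float(out)


def mechanism_rate(h_tablet, r_basal: float, gamma: float,
                   dose: float, weight: float):
    """Surface-area-law release-rate magnitude R*(dose/W)*(W*H/dose)^gamma."""
    h = np.asarray(h_tablet, dtype=float)
    if np.any(h < 0):
        raise ValueError("remaining HPMC must be non-negative")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if weight <= 0 or dose <= 0:
        raise ValueError("dose and weight must be positive")
    out = r_basal * (dose / weight) * (weight * h / dose) ** gamma
    return out if out.ndim else float(out)


def _lambertw_of_exp(log_x):
    """Principal-branch W0(exp(log_x)), safe for large arguments.

    For moderate ``log_x`` this simply evaluates ``lambertw(exp(log_x))``;
    when ``exp(log_x)`` would overflow it solves ``w + log(w) = log_x`` by
    Halley iteration from the asymptotic start ``w0 = L - log(L)``.
    """
    L = np.asarray(log_x, dtype=float)
    out = np.empty_like(L)
    small = L < 650.0
    out[small] = np.real(lambertw(np.exp(L[small])))
    big = ~small
    if np.any(big):
        Lb = L[big]
        w = Lb - np.log(Lb)
        for _ in range(4):  # quadratic convergence; 4 steps ample at L>650
            f = w + np.log(w) - Lb
            w = w - f / (1.0 + 1.0 / w - 0.5 * f / (w * (1.0 + w)))
        out[big] = w
    return out


def analytic_segment_solution(h0: float, vmax: float, km: float,
                              dt: float) -> float:
    """Remaining HPMC after ``dt`` hours of Michaelis-Menten depletion.

    Closed form: ``H(dt) = Km * W0((H0/Km) * exp((H0 - Vmax*dt)/Km))``
    with W0 the principal Lambert W branch.  Overflow-prone arguments
    are evaluated on the log scale.
    """
    if h0 < 0 or dt < 0:
        raise ValueError("h0 and dt must be non-negative")
    if h0 == 0.0 or dt == 0.0:
        return float(h0)
    log_x = np.log(h0 / km) + (h0 - vmax * dt) / km
    return float(km * _lambertw_of_exp(log_x))


def numeric_segment_solution(h0: float, vmax: float, km: float, dt: float,
                             rtol: float = 1e-10,
                             atol: float = 1e-10) -> float:
    """Adaptive Runge-Kutta integration of the Michaelis-Menten ODE."""
    if dt == 0.0 or h0 == 0.0:
        return float(h0)
    sol = solve_ivp(lambda t, y: [-vmax * y[0] / (km + y[0])],
                    (0.0, dt), [h0], method="DOP853", rtol=rtol, atol=atol)
    return float(max(sol.y[0, -1], 0.0))


def _mechanism_segment_solution(h0: float, r_basal: float, gamma: float,
                                dose: float, weight: float,
                                dt: float) -> float:
    """Closed form for the power-law ODE dH/dt = -c * H^gamma."""
    if dt == 0.0 or h0 == 0.0:
        return float(h0)
    c = r_basal * (weight / dose) ** (gamma - 1.0)
    if abs(gamma - 1.0) < 1e-12:
        return float(h0 * np.exp(-c * dt))
    base = h0 ** (1.0 - gamma) - (1.0 - gamma) * c * dt
    if gamma < 1.0 and base <= 0.0:
        return 0.0  # full depletion in finite time
    return float(base ** (1.0 / (1.0 - gamma)))


def solve_release_profile(
    params: StructuralParams,
    timeline: ParamTimeline,
    dose: float,
    times: Sequence[float],
    method: Literal["analytic", "numeric"] = "analytic",
    model: Literal["michaelis-menten", "mechanism"] = "michaelis-menten",
    weight: float = 350.0,
) -> list[ReleaseState]:
    """Solve the erosion profile at the requested times.

    The release clock starts at ``params.tlag``; for the mechanism model
    the timeline's per-segment vmax entries are interpreted as relative
    multipliers on ``r_basal`` (km entries are ignored).
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("times must be sorted and non-negative")
    rel = released_at(params, timeline, dose, t, method=method,
                      model=model, weight=weight)
    return [ReleaseState(float(ti), float(dose - ri), float(ri))
            for ti, ri in zip(t, rel)]


def released_at(
    params: StructuralParams,
    timeline: ParamTimeline,
    dose: float,
    times: np.ndarray,
    method: str = "analytic",
    model: str = "michaelis-menten",
    weight: float = 350.0,
) -> np.ndarray:
    """Released HPMC (mg) at each time; vectorized workhorse."""
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    active = t > params.tlag
    if not np.any(active):
        return out

    bp = np.asarray(timeline.breakpoints, dtype=float)
    seg_pars = list(timeline.segment_params)
    t_act = t[active]
    t_end = float(t_act.max())

    # Boundaries of the constant-parameter stretches intersecting
    # (tlag, t_end]; release runs from tlag, state carried continuously.
    edges = [params.tlag]
    pars = []
    for i in range(bp.size):
        seg_hi = bp[i + 1] if i + 1 < bp.size else np.inf
        if seg_hi <= params.tlag or bp[i] >= t_end:
            continue
        if bp[i] > edges[-1]:
            edges.append(float(bp[i]))
        pars.append(seg_pars[i])
    if not pars:  # all requests before the first covered stretch
        pars = [seg_pars[-1]]
    edges.append(t_end)

    h = float(dose)
    rel_act = np.empty_like(t_act)
    for a, b, (vmax_i, km_i) in zip(edges[:-1], edges[1:], pars):
        in_seg = (t_act > a) & (t_act <= b)
        if np.any(in_seg):
            vals = _segment_vals(h, vmax_i, km_i, t_act[in_seg] - a,
                                 method, model, params, dose, weight)
            rel_act[in_seg] = dose - vals
        if b < t_end:
            h = float(_segment_vals(h, vmax_i, km_i, np.array([b - a]),
                                    method, model, params, dose, weight)[0])
    out[active] = np.clip(rel_act, 0.0, dose)
    return out


def _segment_vals(h0: float, vmax: float, km: float, dts: np.ndarray,
                  method: str, model: str, params: StructuralParams,
                  dose: float, weight: float) -> np.ndarray:
    if model == "mechanism":
        # vmax carries the environment multiplier on the basal rate
        r = params.r_basal * (vmax / params.vmax if params.vmax else 1.0)
        return np.array([_mechanism_segment_solution(
            h0, r, params.gamma, dose, weight, float(dt)) for dt in dts])
    if method == "analytic":
        if h0 == 0.0:
            return np.zeros_like(dts)
        log_x = np.log(h0 / km) + (h0 - vmax * dts) / km
        return km * _lambertw_of_exp(log_x)
    return np.array([numeric_segment_solution(h0, vmax, km, float(dt))
                     for dt in dts])
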