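"""Gastrointestinal environment construction from tablet-location data.

Magnetic marker monitoring reports the tablet location as stomach,
small intestine or colon.  The small intestine is further segmented
into proximal and distal parts by one of three rules, and each segment
is assigned a pH (drawn from literature priors, stomach pH depending on
prandial status) and a mechanical stress expressed as a USP2 paddle
rotation speed equivalent (rpm).  The per-segment (pH, rpm) pairs feed
the covariate model to produce a piecewise-constant (Vmax, Km)
timeline for the erosion ODE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .covariates import CovariateParams, km_from_covariates, vmax_from_covariates
from .formulations import Formulation
from .model_core import ParamTimeline

STOMACH = "stomach"
SMALL_INTESTINE = "small_intestine"
PROXIMAL_SI = "proximal_SI"
DISTAL_SI = "distal_SI"
COLON = "colon"

#: Fractional length of the proximal small intestine used by the
#: fractional-SITT segmentation rule (remainder is distal).
PROXIMAL_SI_FRACTION = 0.45

PH_TRUNC_BOUNDS = (0.5, 9.0)


@dataclass(frozen=True)
class GILocationRecord:
    """Observed tablet transit for one subject-occasion.

    Entry times in hours post dose; the tablet starts in the stomach at
    t = 0.  ``colon_entry`` may be None if the tablet never reached the
    colon before the record ended.
    """

    subject: int
    occasion: int
    prandial: str  # "fasting" | "postprandial"
    si_entry: float
    colon_entry: Optional[float]
    record_end: float = 14.0

    def __post_init__(self) -> None:
        if self.si_entry < 0:
            raise ValueError("small-intestine entry before dosing")
        if self.colon_entry is not None and self.colon_entry < self.si_entry:
            raise ValueError("colon entry precedes small-intestine entry")
        if self.prandial not in ("fasting", "postprandial"):
            raise ValueError(f"unknown prandial status {self.prandial!r}")


@dataclass(frozen=True)
class SegmentedTimeline:
    """Contiguous GI segments with entry times (h)."""

    segments: tuple[str, ...]
    entry_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.entry_times):
            raise ValueError("segments and entry times must align")
        if list(self.entry_times) != sorted(self.entry_times):
            raise ValueError("entry times must be non-decreasing")
        if self.segments[0] != STOMACH or self.entry_times[0] != 0.0:
            raise ValueError("transit must start in the stomach at t = 0")


@dataclass(frozen=True)
class PhPrior:
    """Mean/SD pH per GI segment (stomach split by prandial status).

    Defaults are literature values for a comparable young healthy
    population; draws are truncated to the physiological range.
    """

    stomach_fasting: tuple[float, float] = (1.73, 0.52)
    stomach_postprandial: tuple[float, float] = (4.90, 0.81)
    proximal_si: tuple[float, float] = (6.63, 0.53)
    distal_si: tuple[float, float] = (7.49, 0.46)
    colon: tuple[float, float] = (6.63, 0.67)

    def lookup(self, segment: str, prandial: str) -> tuple[float, float]:
        if segment == STOMACH:
            return (self.stomach_postprandial if prandial == "postprandial"
                    else self.stomach_fasting)
        try:
            return {PROXIMAL_SI: self.proximal_si,
                    DISTAL_SI: self.distal_si,
                    COLON: self.colon}[segment]
        except KeyError:
            raise ValueError(f"unknown GI segment {segment!r}") from None


@dataclass(frozen=True)
class RpmParams:
    """Per-segment mechanical stress, USP2 rotation-speed equivalent."""

    rpm_stomach: float = 39.5
    rpm_proximal_si: float = 93.3
    rpm_distal_si: float = 31.1
    rpm_colon: float = 9.99

    def __post_init__(self) -> None:
        if min(self.rpm_stomach, self.rpm_proximal_si,
               self.rpm_distal_si, self.rpm_colon) <= 0:
            raise ValueError("mechanical stress must be positive")

    def lookup(self, segment: str) -> float:
        try:
            return {STOMACH: self.rpm_stomach,
                    PROXIMAL_SI: self.rpm_proximal_si,
                    DISTAL_SI: self.rpm_distal_si,
                    COLON: self.rpm_colon}[segment]
        except KeyError:
            raise ValueError(f"unknown GI segment {segment!r}") from None


def segment_small_intestine(rec: GILocationRecord,
                            method: str = "fixed_offset_1h",
                            offset: float = 1.0) -> SegmentedTimeline:
    """Split the small-intestine residence into proximal/distal parts.

    ``fractional_sitt`` places the transfer at SI entry + 45% of the
    individual small-intestinal transit time; ``fixed_offset_1h`` (the
    selected rule) at SI entry + 1 h; ``estimated_offset`` at SI entry
    + ``offset``.  If the transfer would fall at or after colon entry
    the distal interval is empty.
    """
    if method == "fractional_sitt":
        if rec.colon_entry is None:
            raise ValueError("fractional_sitt needs an observed colon entry")
        transfer = rec.si_entry + PROXIMAL_SI_FRACTION * (
            rec.colon_entry - rec.si_entry)
    elif method == "fixed_offset_1h":
        transfer = rec.si_entry + 1.0
    elif method == "estimated_offset":
        transfer = rec.si_entry + offset
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    segments = [STOMACH, PROXIMAL_SI]
    entries = [0.0, rec.si_entry]
    end = rec.colon_entry if rec.colon_entry is not None else np.inf
    if transfer < end:
        segments.append(DISTAL_SI)
        entries.append(float(transfer))
    if rec.colon_entry is not None:
        segments.append(COLON)
        entries.append(float(rec.colon_entry))
    return SegmentedTimeline(tuple(segments), tuple(entries))


def draw_segment_ph(segment: str, prandial: str, prior: PhPrior,
                    rng: Optional[np.random.Generator] = None) -> float:
    """One pH value for a segment: truncated-normal draw, or the prior
    mean when ``rng`` is None (deterministic mode)."""
    mean, sd = prior.lookup(segment, prandial)
    if rng is None:
        return mean
    lo, hi = PH_TRUNC_BOUNDS
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def build_environment_timeline(
    seg: SegmentedTimeline,
    prandial: str,
    rpm: RpmParams = RpmParams(),
    prior: PhPrior = PhPrior(),
    rng: Optional[np.random.Generator] = None,
    ph_values: Optional[Sequence[float]] = None,
) -> list[tuple[float, float, float]]:
    """Per-interval (entry_time, pH, rpm) for a segmented transit.

    pH is drawn once per segment (or taken from ``ph_values`` when the
    draws were recorded with the data); only the stomach pH depends on
    prandial status.
    """
    out = []
    for i, (name, entry) in enumerate(zip(seg.segments, seg.entry_times)):
        if ph_values is not None:
            ph = float(ph_values[i])
        else:
            ph = draw_segment_ph(name, prandial, prior, rng)
        out.append((float(entry), ph, rpm.lookup(name)))
    return out


def timeline_from_environment(
    env: Sequence[tuple[float, float, float]],
    cp: CovariateParams,
    formulation: Formulation,
    eta: float = 0.0,
) -> ParamTimeline:
    """Map (entry, pH, rpm) intervals to a (Vmax, Km) parameter timeline."""
    breakpoints = [e[0] for e in env]
    pars = [(vmax_from_covariates(cp, formulation, ph, r, eta),
             km_from_covariates(cp, formulation, ph))
            for _, ph, r in env]
    return ParamTimeline(breakpoints, pars)
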