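"""Hydrophilic matrix tablet formulations.

A formulation is described by its composition in %w/w: high molecular
weight HPMC (Methocel K4M, 303 kDa), low molecular weight HPMC (Methocel
K100LV, 128 kDa), calcium hydrogen phosphate (DCP) filler, iron oxide
label and sodium stearyl fumarate lubricant.  The quantity driving the
erosion model is the HPMC dose in mg, i.e. the total polymer load of the
tablet.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidFormulationError(ValueError):
    """Raised when a formulation cannot form a hydrophilic matrix."""


@dataclass(frozen=True)
class Formulation:
    """Composition of one hydrophilic matrix tablet.

    Parameters
    ----------
    name : str
        Label, e.g. ``"F1"``.
    mk4m_frac : float
        High molecular weight HPMC (Methocel K4M) content, %w/w.
    k100lv_frac : float
        Low molecular weight HPMC (Methocel K100LV) content, %w/w.
    dcp_frac : float
        Calcium hydrogen phosphate (DCP) filler content, %w/w.
    iron_oxide_frac, ssf_frac : float
        Iron oxide label and sodium stearyl fumarate contents, %w/w.
    tablet_weight : float
        Total tablet weight in mg.
    """

    name: str
    mk4m_frac: float
    k100lv_frac: float
    dcp_frac: float
    iron_oxide_frac: float = 1.4
    ssf_frac: float = 1.0
    tablet_weight: float = 350.0

    def __post_init__(self) -> None:
        fracs = (self.mk4m_frac, self.k100lv_frac, self.dcp_frac,
                 self.iron_oxide_frac, self.ssf_frac)
        if any(f < 0 for f in fracs):
            raise InvalidFormulationError(
                f"{self.name}: negative component fraction")
        if sum(fracs) > 100.0 + 1e-9:
            raise InvalidFormulationError(
                f"{self.name}: component fractions exceed 100 %w/w")
        if self.tablet_weight <= 0:
            raise InvalidFormulationError(
                f"{self.name}: non-positive tablet weight")
        if self.mk4m_frac + self.k100lv_frac <= 0:
            raise InvalidFormulationError(
                f"{self.name}: no HPMC, cannot form a hydrophilic matrix")

    @property
    def hpmc_frac(self) -> float:
        """Total HPMC content, %w/w."""
        return self.mk4m_frac + self.k100lv_frac

    @property
    def hpmc_dose(self) -> float:
        """Total HPMC amount in the tablet, mg."""
        return self.hpmc_frac / 100.0 * self.tablet_weight


def hpmc_dose(formulation: Formulation) -> float:
    """HPMC dose (mg) of a formulation: (MK4M% + K100LV%)/100 x weight."""
    return formulation.hpmc_dose


#: The four studied formulations.  F1-F3 carry 40 %w/w total HPMC with a
#: decreasing high molecular weight share; F4 carries 20 %w/w low
#: molecular weight HPMC only, balanced by extra DCP filler.
FORMULATIONS: dict[str, Formulation] = {
    "F1": Formulation("F1", mk4m_frac=23.0, k100lv_frac=17.0, dcp_frac=57.6),
    "F2": Formulation("F2", mk4m_frac=10.0, k100lv_frac=30.0, dcp_frac=57.6),
    "F3": Formulation("F3", mk4m_frac=0.0, k100lv_frac=40.0, dcp_frac=57.6),
    "F4": Formulation("F4", mk4m_frac=0.0, k100lv_frac=20.0, dcp_frac=77.6),
}
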