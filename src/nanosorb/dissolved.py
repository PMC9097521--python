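"""Reactive area of dissolved silica and the particulate/dissolved competition.

Amorphous silica is sparingly soluble (0.012% w/v in water and the
electrolyte, i.e. about 0.002 mol dm^-3 as SiO2), so the supernatant of
a dispersion carries molecular SiO2 species that compete with the
particles for the monolayer.  Treating each dissolved SiO2 tetrahedron
as close-packed flat on the lipid with its triangular base (O-O
distance 0.26 nm) gives the dissolved species a reactive area directly
comparable with the particulate reactive area A.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, ModelConstants

NM2_PER_CM2 = 1.0e14

DEFAULT_OO_DISTANCE_NM = 0.26
DEFAULT_SOLUBILITY_PERCENT_WV = 0.012


def percent_wv_to_molar(percent: float, molar_mass: float) -> float:
    """Convert a % w/v (g per 100 cm^3) solubility to mol dm^-3.

    percent/100 g cm^-3 = percent * 10 g dm^-3, divided by the molar
    mass.
    """
    if percent < 0:
        raise ValueError("percent w/v must be nonnegative")
    if not molar_mass > 0:
        raise ValueError(f"molar mass must be strictly positive, got {molar_mass!r}")
    return percent * 10.0 / molar_mass


def tetrahedron_base_area(oo_distance_nm: float) -> float:
    """Base area of an SiO4 tetrahedron in nm^2.

    Equilateral triangle of side equal to the O-O distance:
    (sqrt(3)/4) d^2.
    """
    if not oo_distance_nm > 0:
        raise ValueError("O-O distance must be strictly positive")
    return (math.sqrt(3.0) / 4.0) * oo_distance_nm**2


def dissolved_reactive_area(
    moles: float,
    footprint_nm2: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Reactive area (cm^2) of dissolved SiO2 close-packed on the lipid.

    moles * N_A * footprint, with the nm^2 footprint converted to cm^2.
    """
    if moles < 0:
        raise ValueError("moles must be nonnegative")
    if footprint_nm2 < 0:
        raise ValueError("footprint must be nonnegative")
    return moles * const.molecules_per_mol * footprint_nm2 / NM2_PER_CM2


def competition_ratio(particulate_area: float, dissolved_area: float) -> float:
    """Particulate over dissolved reactive area; > 1 means particulate-dominated."""
    if not dissolved_area > 0:
        raise ValueError("dissolved area must be strictly positive")
    return particulate_area / dissolved_area


@dataclass(frozen=True)
class DissolvedSilicaSpec:
    """Solubility and footprint inputs for the supernatant arithmetic.

    Supplying ``footprint_area_nm2`` explicitly overrides the value
    derived from ``oo_distance_nm``; when both are given they must be
    consistent with the equilateral-triangle formula.
    """

    solubility_percent_wv: float = DEFAULT_SOLUBILITY_PERCENT_WV
    oo_distance_nm: float = DEFAULT_OO_DISTANCE_NM
    footprint_area_nm2: float | None = None

    def __post_init__(self) -> None:
        if not self.solubility_percent_wv > 0:
            raise ValueError("solubility must be strictly positive")
        derived = tetrahedron_base_area(self.oo_distance_nm)
        if self.footprint_area_nm2 is not None:
            if not self.footprint_area_nm2 > 0:
                raise ValueError("footprint area must be strictly positive")
            if abs(self.footprint_area_nm2 - derived) / derived > 0.25:
                raise ValueError(
                    f"footprint {self.footprint_area_nm2} nm^2 inconsistent with "
                    f"O-O distance {self.oo_distance_nm} nm (expected ~{derived:.4f})"
                )

    @property
    def footprint(self) -> float:
        if self.footprint_area_nm2 is not None:
            return self.footprint_area_nm2
        return tetrahedron_base_area(self.oo_distance_nm)

    def molar_concentration(self, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
        return percent_wv_to_molar(self.solubility_percent_wv, const.silica_molar_mass)

    def report(
        self,
        particulate_area: float | None = None,
        const: ModelConstants = DEFAULT_CONSTANTS,
    ) -> dict:
        """Full supernatant arithmetic as a plain dict (JSON-ready)."""
        molar = self.molar_concentration(const)
        area = dissolved_reactive_area(molar, self.footprint, const)
        out = {
            "solubility_percent_wv": self.solubility_percent_wv,
            "molar_concentration_mol_per_dm3": molar,
            "oo_distance_nm": self.oo_distance_nm,
            "footprint_nm2": self.footprint,
            "dissolved_reactive_area_cm2_per_dm3": area,
        }
        if particulate_area is not None:
            ratio = competition_ratio(particulate_area, area)
            out["particulate_reactive_area_cm2"] = particulate_area
            out["competition_ratio"] = ratio
            out["particulate_dominated"] = ratio > 1.0
        return out
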