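"""Physical and model constants shared by every calculation.

All lengths are held internally in cm because every closed-form
expression of the reaction-layer model is written in cm; nanometre
values are converted once at the input boundary (:func:`nm_to_cm`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields

NM_PER_CM = 1.0e7

#: Sanity bounds for a nanoparticle hydrodynamic radius, in cm.
RADIUS_SANITY_CM = (1.0e-7, 1.0e-4)


def nm_to_cm(value_nm: float) -> float:
    """Convert a length from nm to cm."""
    return value_nm / NM_PER_CM


def cm_to_nm(value_cm: float) -> float:
    """Convert a length from cm to nm."""
    return value_cm * NM_PER_CM


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the reaction-layer adsorption model.

    Attributes
    ----------
    reaction_layer_thickness_h : float
        Thickness of the interfacial "reaction layer" around a silica
        particle within which SiO2 units interact with the lipid
        monolayer, in cm.
    silica_density : float
        Density of amorphous silica, g cm^-3.
    silica_molar_mass : float
        Molar mass of SiO2, g mol^-1.
    full_suppression_current : float
        Capacitance current peak-2 height that is lost when the
        monolayer is completely covered by confluent reactive areas,
        in uA.
    molecules_per_mmol : float
        Number of molecules in one mmol (Avogadro / 1000).  Kept at
        three significant figures by default so worked examples
        reproduce at their printed precision; configurable.
    molecules_per_mol : float
        Number of molecules in one mol; must equal
        ``1000 * molecules_per_mmol``.
    """

    reaction_layer_thickness_h: float = 3.23e-7
    silica_density: float = 2.196
    silica_molar_mass: float = 60.08
    full_suppression_current: float = 32.1
    molecules_per_mmol: float = 6.02e20
    molecules_per_mol: float = field(default=6.02e23)

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")
        ratio = self.molecules_per_mol / (1000.0 * self.molecules_per_mmol)
        if abs(ratio - 1.0) > 1e-9:
            raise ValueError(
                "molecules_per_mol must equal 1000 * molecules_per_mmol "
                f"(got {self.molecules_per_mol} vs {self.molecules_per_mmol})"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConstants":
        """Build from a ``constants:`` config block; missing keys take defaults."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown constant name(s): {sorted(unknown)}")
        merged = dict(data)
        # keep the mol/mmol pair consistent if only one is supplied
        if "molecules_per_mmol" in merged and "molecules_per_mol" not in merged:
            merged["molecules_per_mol"] = 1000.0 * merged["molecules_per_mmol"]
        elif "molecules_per_mol" in merged and "molecules_per_mmol" not in merged:
            merged["molecules_per_mmol"] = merged["molecules_per_mol"] / 1000.0
        return cls(**merged)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_CONSTANTS = ModelConstants()
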