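"""Closed-form geometry of the reaction-layer adsorption model.

A silica nanoparticle of radius ``R`` sitting on a DOPC monolayer
interacts with the lipid through a thin interfacial shell of thickness
``h`` (the reaction layer).  The zone of the particle surface lying
within that shell projects a per-particle *reactive area*
``pi * (2Rh + h^2)``; summing over the number of particles containing
one mmol of SiO2 gives the specific reactive area ``A`` in
cm^2 mmol^-1, the model's currency for adsorption capacity.  The same
geometry fixes the hexagonally close-packed footprint ``SA`` of one
mmol of particles and the size-specific maximum depression of the
capacitance current peak.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, RADIUS_SANITY_CM, ModelConstants

_SQRT3 = math.sqrt(3.0)


def _check_radius(R: float) -> None:
    if not R > 0:
        raise ValueError(f"particle radius must be strictly positive, got {R!r}")


@dataclass(frozen=True)
class Particle:
    """A nanoparticle dispersion characterised by one effective radius.

    ``radius_R`` is the hydrodynamic radius in cm.  Radii outside the
    plausible nano-range are accepted but flagged via :attr:`in_bounds`
    so unit mix-ups (nm passed as cm) surface early.
    """

    radius_R: float
    label: str = ""

    def __post_init__(self) -> None:
        _check_radius(self.radius_R)

    @property
    def in_bounds(self) -> bool:
        lo, hi = RADIUS_SANITY_CM
        return lo <= self.radius_R <= hi


@dataclass(frozen=True)
class ReactiveAreaResult:
    """All geometric quantities of the model evaluated at one radius."""

    radius_R: float
    per_particle_area: float          # cm^2
    per_mmol_area_A: float            # cm^2 mmol^-1 (SiO2 basis)
    particles_per_mmol: float         # mmol^-1
    molecules_per_particle_Ctr: float # count
    close_packed_area_SA: float       # cm^2 mmol^-1 (particle basis)
    max_depression_model: float       # uA
    v_model: float                    # uA cm^2 mmol^-1


def molecules_per_particle(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Number of SiO2 molecules in one particle of radius ``R`` (cm).

    C_tr = N_A * (4/3) pi R^3 * density / molar_mass.
    """
    _check_radius(R)
    volume = (4.0 / 3.0) * math.pi * R**3
    return const.molecules_per_mol * volume * const.silica_density / const.silica_molar_mass


def reactive_area_per_particle(R: float, h: float) -> float:
    """Reactive area of a single particle, pi(2Rh + h^2), in cm^2.

    The band of particle surface within a shell of thickness ``h``
    above the lipid plane; vanishes with the reaction layer (h = 0).
    """
    _check_radius(R)
    if h < 0:
        raise ValueError(f"reaction-layer thickness must be >= 0, got {h!r}")
    return math.pi * (2.0 * R * h + h**2)


def particles_per_mmol(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Number of particles containing 1 mmol of SiO2 (mass bookkeeping)."""
    _check_radius(R)
    mass_per_particle = (4.0 / 3.0) * math.pi * R**3 * const.silica_density
    return (const.silica_molar_mass / 1000.0) / mass_per_particle


def reactive_area_per_mmol(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Specific reactive area A in cm^2 per mmol of SiO2.

    Per-particle reactive area times the number of particles holding
    one mmol of SiO2; strictly decreasing in R once R >> h because the
    reactive band grows like R while the per-particle mass grows like
    R^3.
    """
    a_particle = reactive_area_per_particle(R, const.reaction_layer_thickness_h)
    return a_particle * particles_per_mmol(R, const)


def close_packed_area_per_mmol(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Hexagonally close-packed footprint SA of 1 mmol of particles, cm^2.

    SA = N_mmol * 2 sqrt(3) R^2; its reciprocal is the close-packed
    particle coverage per cm^2.
    """
    _check_radius(R)
    return const.molecules_per_mmol * 2.0 * _SQRT3 * R**2


def depression_ratio_uncapped(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Uncapped area ratio pi(2Rh + h^2) / (2 sqrt(3) R^2)."""
    h = const.reaction_layer_thickness_h
    return reactive_area_per_particle(R, h) / (2.0 * _SQRT3 * R**2)


def max_depression_model(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Size-specific maximum peak depression Delta_I_max(R), uA.

    full_suppression_current * min(1, pi(2Rh + h^2) / (2 sqrt(3) R^2)).
    Below the crossover radius the reactive areas of close-packed
    particles are confluent and the depression saturates at the full
    suppression current.
    """
    ratio = depression_ratio_uncapped(R, const)
    return const.full_suppression_current * min(1.0, ratio)


def cap_radius(const: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Radius at which the depression ratio crosses 1 (saturation onset).

    Positive root of 2 sqrt(3) R^2 - 2 pi h R - pi h^2 = 0.
    """
    h = const.reaction_layer_thickness_h
    a = 2.0 * _SQRT3
    b = -2.0 * math.pi * h
    c = -math.pi * h**2
    return (-b + math.sqrt(b**2 - 4.0 * a * c)) / (2.0 * a)


def v_factor(
    R: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
    max_depression: float | None = None,
) -> float:
    """The v factor, uA cm^2 mmol^-1: maximum peak depression times SA.

    With ``max_depression`` absent the model form is returned, which
    collapses to ``full_suppression_current * pi(2Rh + h^2) * N_mmol``
    (the uncapped depression times SA).  Supplying an experimental
    maximum depression gives the experimental variant.
    """
    _check_radius(R)
    if max_depression is None:
        a_particle = reactive_area_per_particle(R, const.reaction_layer_thickness_h)
        return const.full_suppression_current * a_particle * const.molecules_per_mmol
    if not 0.0 < max_depression <= const.full_suppression_current:
        raise ValueError(
            "max_depression must lie in (0, full_suppression_current], "
            f"got {max_depression!r}"
        )
    return max_depression * close_packed_area_per_mmol(R, const)


def reactive_area_result(R: float, const: ModelConstants = DEFAULT_CONSTANTS) -> ReactiveAreaResult:
    """Evaluate every geometric quantity of the model at one radius."""
    return ReactiveAreaResult(
        radius_R=R,
        per_particle_area=reactive_area_per_particle(R, const.reaction_layer_thickness_h),
        per_mmol_area_A=reactive_area_per_mmol(R, const),
        particles_per_mmol=particles_per_mmol(R, const),
        molecules_per_particle_Ctr=molecules_per_particle(R, const),
        close_packed_area_SA=close_packed_area_per_mmol(R, const),
        max_depression_model=max_depression_model(R, const),
        v_model=v_factor(R, const),
    )
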