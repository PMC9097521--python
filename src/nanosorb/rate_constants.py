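"""Heterogeneous adsorption rate constants from normalized rates.

Two derivations give the rate constant in cm s^-1:

* bottom-up, k1: the slope of k' versus reactive area A, times 1000
  (mmol dm^-3 -> mmol cm^-3), divided by the full-suppression current.
* top-down, k2: per particle size,
  ``k2 = k' * 1000 * C_tr(R) / v(R)`` with v either the experimental
  (measured maximum peak depression times SA) or the model variant.

Substituting the corrected normalized rate k'_cor = slope * A(R) into
the top-down formula with the model v collapses, algebraically, to the
bottom-up expression — k2cor is size-independent and equal to k1.  The
module computes both routes independently so that identity is a
checkable property, not an assumption.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, RADIUS_SANITY_CM, ModelConstants
from . import geometry


@dataclass(frozen=True)
class RateConstant:
    """A rate constant value with its propagated standard deviation."""

    value: float  # cm s^-1
    sd: float     # cm s^-1


@dataclass(frozen=True)
class K2corTable:
    """Per-size k2cor values with their mean and spread across sizes."""

    radii: tuple[float, ...]
    values: tuple[float, ...]
    mean: float
    sd: float
    single_radius: bool


@dataclass(frozen=True)
class RatioDiagnostics:
    """Per-size k'/k'_cor and k2/k2cor ratios with propagated error bands.

    The two series are computed through independent routes and must
    coincide; a departure indicates an inconsistency between the
    supplied per-size k2 values and the k' they were derived from.
    """

    radii: tuple[float, ...]
    ratio_kprime: tuple[float, ...]
    ratio_k2: tuple[float, ...]
    ratio_sd: tuple[float, ...]


def propagate_sd(value: float, components: Sequence[tuple[float, float]]) -> float:
    """First-order SD of a product/quotient of independent factors.

    ``components`` is a sequence of (component_value, component_sd)
    pairs entering multiplicatively; relative variances add in
    quadrature:  sd(out)/|out| = sqrt(sum (sd_i / value_i)^2).
    """
    rel_var = 0.0
    for comp_value, comp_sd in components:
        if comp_sd < 0:
            raise ValueError(f"component SD must be nonnegative, got {comp_sd!r}")
        if comp_sd == 0.0:
            continue
        if comp_value == 0.0:
            raise ValueError("cannot propagate a relative SD through a zero-valued factor")
        rel_var += (comp_sd / comp_value) ** 2
    return abs(value) * math.sqrt(rel_var)


def k1_bottom_up(
    slope: float,
    slope_sd: float = 0.0,
    const: ModelConstants = DEFAULT_CONSTANTS,
) -> RateConstant:
    """Bottom-up rate constant k1 = 1000 * slope / full-suppression current.

    ``slope`` is the k'-vs-A slope (uA dm^3 cm^-2 s^-1, printed as
    uA cm s^-1 once the 1000x dm^3 -> cm^3 factor is absorbed); the SD
    scales identically.
    """
    if not slope > 0:
        raise ValueError(f"slope must be strictly positive, got {slope!r}")
    if slope_sd < 0:
        raise ValueError("slope SD must be nonnegative")
    scale = 1000.0 / const.full_suppression_current
    return RateConstant(value=scale * slope, sd=scale * slope_sd)


def k2_top_down(
    k_prime: float,
    R: float,
    v: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
    k_prime_sd: float = 0.0,
    v_sd: float = 0.0,
) -> RateConstant:
    """Top-down rate constant k2 = k' * 1000 * C_tr(R) / v at one size.

    The 1000 converts the mmol dm^-3 basis of k' to mmol cm^-3; C_tr
    converts the molecule basis of k' to the particle basis of v.  The
    caller chooses v: :func:`nanosorb.geometry.v_factor` with an
    experimental maximum depression, or the model variant.
    """
    if k_prime < 0:
        raise ValueError("k' must be nonnegative")
    if not v > 0:
        raise ValueError(f"v factor must be strictly positive, got {v!r}")
    value = k_prime * 1000.0 * geometry.molecules_per_particle(R, const) / v
    sd = propagate_sd(value, [(k_prime, k_prime_sd), (v, v_sd)]) if k_prime > 0 else 0.0
    return RateConstant(value=value, sd=sd)


def kprime_cor(
    slope: float,
    R: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Corrected normalized rate k'_cor(R) = slope * A(R).

    Replaces the measured per-size k' by its value on the fitted
    k'-vs-A line, removing per-size scatter before the top-down
    conversion.
    """
    if not slope > 0:
        raise ValueError(f"slope must be strictly positive, got {slope!r}")
    return slope * geometry.reactive_area_per_mmol(R, const)


def _check_radii_cm(radii: Sequence[float]) -> None:
    hi = RADIUS_SANITY_CM[1]
    bad = [R for R in radii if R > hi]
    if bad:
        raise ValueError(
            f"radii {bad} exceed {hi} cm; nm values passed where cm expected?"
        )


def k2cor_table(
    slope: float,
    radii: Sequence[float],
    const: ModelConstants = DEFAULT_CONSTANTS,
) -> K2corTable:
    """Evaluate the k'_cor -> top-down chain over a radius grid.

    Each entry is k2 evaluated at k' = k'_cor(R) with the model v; the
    chain is algebraically size-independent, so the spread across
    radii is a numerical diagnostic (zero up to floating point).
    """
    radii = list(radii)
    if not radii:
        raise ValueError("radius list must be nonempty")
    _check_radii_cm(radii)
    values = []
    for R in radii:
        kp = kprime_cor(slope, R, const)
        v = geometry.v_factor(R, const)
        values.append(k2_top_down(kp, R, v, const).value)
    arr = np.asarray(values)
    single = len(radii) == 1
    return K2corTable(
        radii=tuple(radii),
        values=tuple(values),
        mean=float(arr.mean()),
        sd=0.0 if single else float(arr.std(ddof=1)),
        single_radius=single,
    )


def ratio_diagnostics(
    k_prime_per_size: Sequence[float],
    slope: float,
    radii: Sequence[float],
    k2_per_size: Sequence[float],
    const: ModelConstants = DEFAULT_CONSTANTS,
    k_prime_sd_per_size: Sequence[float] | None = None,
) -> RatioDiagnostics:
    """Per-size k'/k'_cor and k2/k2cor, computed through separate routes.

    ``k2_per_size`` must be the model-v top-down constants derived from
    ``k_prime_per_size``; both ratio series then measure the same
    departure of each size from the fitted k'-vs-A line and coincide.
    Error bands propagate the per-size k' SDs (the k'_cor denominator
    is treated as exact, its uncertainty living in the slope).
    """
    n = len(radii)
    if not (len(k_prime_per_size) == len(k2_per_size) == n):
        raise ValueError("k', k2 and radius lists must have matching lengths")
    if k_prime_sd_per_size is None:
        k_prime_sd_per_size = [0.0] * n
    elif len(k_prime_sd_per_size) != n:
        raise ValueError("k' SD list length must match radii")

    table = k2cor_table(slope, radii, const)
    ratios_kp, ratios_k2, sds = [], [], []
    for kp, kp_sd, k2, k2c, R in zip(
        k_prime_per_size, k_prime_sd_per_size, k2_per_size, table.values, radii
    ):
        kpc = kprime_cor(slope, R, const)
        r_kp = kp / kpc
        r_k2 = k2 / k2c
        ratios_kp.append(r_kp)
        ratios_k2.append(r_k2)
        sds.append(propagate_sd(r_kp, [(kp, kp_sd)]) if kp != 0 else 0.0)
    return RatioDiagnostics(
        radii=tuple(radii),
        ratio_kprime=tuple(ratios_kp),
        ratio_k2=tuple(ratios_k2),
        ratio_sd=tuple(sds),
    )
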