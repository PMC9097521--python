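"""Seeded synthetic adsorption-trace studies with a known rate constant.

The generator emulates the statistical structure the analysis chain
assumes: at each particle radius the normalized rate k' follows from a
single ground-truth heterogeneous rate constant through the
reaction-layer geometry; every trace declines at exactly k' * C_np
during its initial linear phase and then relaxes exponentially to the
size-specific maximum-depression plateau; noise is additive,
homoscedastic and Gaussian.  Because the truth is known, the full
pipeline's recovery of the rate constant is testable end to end.

The default study design mirrors a range-finding experiment: doses are
scaled per particle size so that the top concentration's linear phase
still covers the standard 50 s rate window (small particles suppress
the peak far faster per mmol than large ones), capped at the study's
12 mmol dm^-3 ceiling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ModelConstants, cm_to_nm, nm_to_cm
from . import geometry
from .rates import AdsorptionTrace

#: Radius grid (nm) of the default study design: six sizes spanning the
#: studied 6.75-86 nm range.
DEFAULT_RADII_NM = (6.75, 15.0, 25.0, 46.0, 66.0, 86.0)
#: Concentration grid as fractions of the per-size maximum dose.
DEFAULT_CONC_FRACTIONS = (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6, 1.0)
MAX_CONCENTRATION = 12.0              # mmol dm^-3, ceiling of the studied range
DEFAULT_TRUE_RATE_CONSTANT = 4.22e-4  # cm s^-1
DEFAULT_NOISE_SD = 0.1                # uA
DEFAULT_DT = 1.0                      # s
DEFAULT_DURATION = 300.0              # s
#: Fraction of the maximum depression reached before the transient
#: leaves its linear phase.
DEFAULT_LINEAR_FRACTION = 0.5
#: The linear phase of the top dose must last at least this long (s),
#: covering the standard rate-extraction window.
DEFAULT_LINEAR_HORIZON = 50.0


def kprime_from_rate_constant(
    k_het: float,
    R: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Normalized rate k' implied by a heterogeneous rate constant.

    Inverse of the top-down conversion:
    k' = k_het * v_model(R) / (1000 * C_tr(R)); proportional to the
    reactive area A(R) at fixed k_het.
    """
    if k_het < 0:
        raise ValueError("rate constant must be nonnegative")
    v = geometry.v_factor(R, const)
    return k_het * v / (1000.0 * geometry.molecules_per_particle(R, const))


def max_linear_concentration(
    k_het: float,
    R: float,
    const: ModelConstants = DEFAULT_CONSTANTS,
    linear_fraction: float = DEFAULT_LINEAR_FRACTION,
    linear_horizon: float = DEFAULT_LINEAR_HORIZON,
    ceiling: float = MAX_CONCENTRATION,
) -> float:
    """Largest dose whose linear decline outlasts the rate window.

    The linear phase ends once the depression reaches
    ``linear_fraction * dImax(R)``, i.e. after
    ``linear_fraction * dImax / (k' C)`` seconds; solving for C at
    ``linear_horizon`` and capping at the study ceiling.
    """
    k_prime = kprime_from_rate_constant(k_het, R, const)
    if k_prime == 0.0:
        return ceiling
    d_imax = geometry.max_depression_model(R, const)
    return min(ceiling, linear_fraction * d_imax / (k_prime * linear_horizon))


def _signal(
    times: np.ndarray,
    baseline: float,
    d_imax: float,
    rate: float,
    linear_fraction: float,
) -> np.ndarray:
    """Noise-free peak height: linear decline, then exponential plateau.

    Depression grows as ``rate * t`` until ``linear_fraction * d_imax``,
    then approaches ``d_imax`` exponentially with matching value and
    slope at the junction, so the initial slope is exactly ``-rate``
    and the depression never exceeds ``d_imax``.
    """
    if rate <= 0.0:
        return np.full_like(times, baseline)
    t_switch = linear_fraction * d_imax / rate
    tail = (1.0 - linear_fraction) * d_imax
    depression = np.where(
        times <= t_switch,
        rate * times,
        d_imax - tail * np.exp(-rate * (times - t_switch) / tail),
    )
    return baseline - depression


def generate_trace(
    R: float,
    C: float,
    k_het: float,
    noise_sd: float = DEFAULT_NOISE_SD,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    seed: int | np.random.SeedSequence = 0,
    const: ModelConstants = DEFAULT_CONSTANTS,
    baseline_peak: float | None = None,
    linear_fraction: float = DEFAULT_LINEAR_FRACTION,
    replicate_id: str = "r1",
) -> AdsorptionTrace:
    """One noisy peak-height trace at radius ``R`` (cm) and dose ``C``.

    The noise-free signal declines at exactly k'(R) * C during its
    linear phase and plateaus at the size-specific maximum depression.
    """
    if not dt > 0:
        raise ValueError("dt must be strictly positive")
    if duration < dt:
        raise ValueError("duration must cover at least one sampling step")
    if noise_sd < 0:
        raise ValueError("noise SD must be nonnegative")
    if not 0.0 < linear_fraction < 1.0:
        raise ValueError("linear_fraction must lie in (0, 1)")
    baseline = const.full_suppression_current if baseline_peak is None else baseline_peak
    d_imax = geometry.max_depression_model(R, const)
    rate = kprime_from_rate_constant(k_het, R, const) * C
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    signal = _signal(times, baseline, d_imax, rate, linear_fraction)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heights = signal + rng.normal(0.0, noise_sd, size=times.size)
    else:
        heights = signal
    return AdsorptionTrace(
        times=times,
        peak_heights=heights,
        concentration_Cnp=C,
        radius_R=R,
        replicate_id=replicate_id,
    )


@dataclass(frozen=True)
class SyntheticStudy:
    """A seeded grid of traces with its ground truth recorded."""

    true_rate_constant: float
    radii: tuple[float, ...]                          # cm
    concentrations: tuple[tuple[float, ...], ...]     # mmol dm^-3, per size
    replicates: int
    noise_sd: float
    sampling_dt: float
    duration: float
    baseline_peak: float
    seed: int
    traces: tuple[AdsorptionTrace, ...] = field(repr=False)

    def manifest(self) -> pd.DataFrame:
        """Manifest table matching the trace order, radii in nm."""
        rows = [
            {
                "trace_file": _trace_filename(t, i),
                "radius_nm": cm_to_nm(t.radius_R),
                "conc_mmol_per_dm3": t.concentration_Cnp,
                "replicate_id": t.replicate_id,
            }
            for i, t in enumerate(self.traces)
        ]
        return pd.DataFrame(rows)

    def params(self) -> dict:
        return {
            "true_rate_constant_cm_per_s": self.true_rate_constant,
            "radii_nm": [cm_to_nm(R) for R in self.radii],
            "concentrations_mmol_per_dm3": [list(c) for c in self.concentrations],
            "replicates": self.replicates,
            "noise_sd_uA": self.noise_sd,
            "sampling_dt_s": self.sampling_dt,
            "duration_s": self.duration,
            "baseline_peak_uA": self.baseline_peak,
            "seed": self.seed,
        }


def _trace_filename(trace: AdsorptionTrace, index: int) -> str:
    r_nm = cm_to_nm(trace.radius_R)
    return (
        f"trace_{index:03d}_R{r_nm:g}nm_C{trace.concentration_Cnp:.5g}"
        f"_{trace.replicate_id}.csv"
    )


def generate_study(
    k_het: float = DEFAULT_TRUE_RATE_CONSTANT,
    radii_nm: tuple[float, ...] = DEFAULT_RADII_NM,
    concentrations: tuple[float, ...] | None = None,
    replicates: int = 1,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    dt: float = DEFAULT_DT,
    duration: float = DEFAULT_DURATION,
    const: ModelConstants = DEFAULT_CONSTANTS,
    linear_fraction: float = DEFAULT_LINEAR_FRACTION,
) -> SyntheticStudy:
    """One trace per (radius, concentration, replicate) cell.

    With ``concentrations`` omitted each size gets its range-found
    default grid (six equal fractions of :func:`max_linear_concentration`);
    an explicit grid is applied to every size as given.  Each trace
    draws its noise from a sub-seed derived deterministically from the
    master seed and the cell indices, so any single trace is
    reproducible in isolation and the whole study is bit-reproducible
    from its seed.
    """
    if not radii_nm or replicates < 1:
        raise ValueError("radius grid and replicates must be nonempty")
    if concentrations is not None and len(concentrations) == 0:
        raise ValueError("concentration grid must be nonempty")
    radii_cm = tuple(nm_to_cm(r) for r in radii_nm)
    conc_grids = []
    for R in radii_cm:
        if concentrations is not None:
            conc_grids.append(tuple(concentrations))
        else:
            c_max = max_linear_concentration(
                k_het, R, const, linear_fraction=linear_fraction
            )
            conc_grids.append(tuple(f * c_max for f in DEFAULT_CONC_FRACTIONS))
    traces = []
    for i, (R, grid) in enumerate(zip(radii_cm, conc_grids)):
        for j, C in enumerate(grid):
            for rep in range(replicates):
                sub = np.random.SeedSequence([int(seed), i, j, rep])
                traces.append(
                    generate_trace(
                        R=R,
                        C=C,
                        k_het=k_het,
                        noise_sd=noise_sd,
                        dt=dt,
                        duration=duration,
                        seed=sub,
                        const=const,
                        linear_fraction=linear_fraction,
                        replicate_id=f"r{rep + 1}",
                    )
                )
    return SyntheticStudy(
        true_rate_constant=k_het,
        radii=radii_cm,
        concentrations=tuple(conc_grids),
        replicates=replicates,
        noise_sd=noise_sd,
        sampling_dt=dt,
        duration=duration,
        baseline_peak=const.full_suppression_current,
        seed=int(seed),
        traces=tuple(traces),
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write trace CSVs plus the manifest; returns the manifest path.

    Files use exactly the layout the rate-extraction stage reads:
    per-trace CSVs with columns ``time_s, peak2_uA`` and a manifest
    with ``trace_file, radius_nm, conc_mmol_per_dm3, replicate_id``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = study.manifest()
    for fname, trace in zip(manifest["trace_file"], study.traces):
        pd.DataFrame({"time_s": trace.times, "peak2_uA": trace.peak_heights}).to_csv(
            out_dir / fname, index=False
        )
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
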