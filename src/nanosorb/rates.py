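"""Initial-rate and normalized-rate extraction from peak-height traces.

The raw observable is the height of capacitance current peak 2 versus
time during exposure of a DOPC monolayer to a nanoparticle dispersion.
Adsorption suppresses the peak, so the initial rate of *decrease* of
the peak height, V (uA s^-1), measures the initial adsorption rate.
Dividing the slope of V versus dispersion concentration C_np gives the
normalized rate k' (uA mmol^-1 dm^3 s^-1) for each particle size, and
regressing k' on the specific reactive area A yields the single slope
from which the size-independent rate constant follows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_RATE_WINDOW = (0.0, 50.0)


class InsufficientDataError(ValueError):
    """Too few points for the requested fit."""


class DegenerateDesignError(ValueError):
    """Predictor values do not span a nonzero range."""


@dataclass(frozen=True)
class AdsorptionTrace:
    """One peak-2-height-versus-time record for a single exposure.

    ``times`` in s (strictly increasing), ``peak_heights`` in uA
    (baseline-corrected peak heights, nonnegative), ``concentration_Cnp``
    in mmol dm^-3 of SiO2, ``radius_R`` in cm.
    """

    times: np.ndarray
    peak_heights: np.ndarray
    concentration_Cnp: float
    radius_R: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        heights = np.asarray(self.peak_heights, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "peak_heights", heights)
        if times.shape != heights.shape or times.ndim != 1:
            raise ValueError("times and peak_heights must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.concentration_Cnp < 0:
            raise ValueError("concentration must be nonnegative")
        if not self.radius_R > 0:
            raise ValueError("radius must be strictly positive")


@dataclass(frozen=True)
class InitialRate:
    """Initial rate of peak-height decrease, V, with its fit uncertainty.

    Positive V means the peak is being suppressed (adsorption).
    ``V_sd`` is the standard error of the fitted slope.
    """

    V: float
    V_sd: float
    window: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class NormalizedRate:
    """k': slope of V versus C_np at one particle size, with diagnostics.

    The intercept of the free-intercept fit is retained as a
    diagnostic; for an adsorbing system it should be close to zero.
    """

    k_prime: float
    k_prime_sd: float
    r_squared: float
    radius_R: float
    n_concentrations: int
    intercept: float = 0.0
    intercept_sd: float = 0.0


@dataclass(frozen=True)
class SlopeFit:
    """Least-squares slope of k' versus reactive area A.

    The slope carries units uA dm^3 cm^-2 s^-1; multiplying by 1000
    (dm^3 -> cm^3) puts it on the uA cm s^-1 scale used for the
    bottom-up rate constant.
    """

    slope: float
    slope_sd: float
    r_squared: float
    intercept: float
    n_points: int
    weighted: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Slope, slope SE, intercept, intercept SE, r^2 of y on x (free intercept)."""
    if np.ptp(y) == 0:
        # constant response: exact zero-slope fit, no residual scatter
        return 0.0, 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    # two points fit exactly: the residual df is zero, report zero SE
    if x.size == 2:
        return float(res.slope), 0.0, float(res.intercept), 0.0, 1.0
    return (
        float(res.slope),
        float(res.stderr),
        float(res.intercept),
        float(res.intercept_stderr),
        r2,
    )


def initial_rate(
    trace: AdsorptionTrace,
    window: tuple[float, float] = DEFAULT_RATE_WINDOW,
) -> InitialRate:
    """Initial adsorption rate V from the early linear part of a trace.

    Ordinary least squares of peak height on time restricted to
    ``window`` (default the first 50 s); V is minus the fitted slope so
    that peak suppression gives positive V.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window start must precede end, got {window!r}")
    mask = (trace.times >= lo) & (trace.times <= hi)
    n = int(mask.sum())
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 samples inside the rate window {window}, found {n}"
        )
    slope, slope_sd, _, _, _ = _ols_line(trace.times[mask], trace.peak_heights[mask])
    return InitialRate(V=-slope, V_sd=slope_sd, window=(lo, hi), n_points=n)


def normalized_rate(
    rates: Sequence[tuple[float, float]],
    radius_R: float,
) -> NormalizedRate:
    """k' as the free-intercept OLS slope of V on C_np at one size.

    ``rates`` is a sequence of (C_np in mmol dm^-3, V in uA s^-1)
    pairs; at least three distinct concentrations spanning a nonzero
    range are required.
    """
    arr = np.asarray(rates, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError(
            "need >= 3 (concentration, rate) pairs, got "
            f"{0 if arr.ndim != 2 else arr.shape[0]}"
        )
    conc, V = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise DegenerateDesignError("all concentrations are equal; slope is undefined")
    slope, slope_sd, intercept, intercept_sd, r2 = _ols_line(conc, V)
    return NormalizedRate(
        k_prime=slope,
        k_prime_sd=slope_sd,
        r_squared=r2,
        radius_R=radius_R,
        n_concentrations=int(np.unique(conc).size),
        intercept=intercept,
        intercept_sd=intercept_sd,
    )


def fit_kprime_vs_area(
    series: Sequence[tuple[float, float, float]],
    weighted: bool = False,
) -> SlopeFit:
    """Regress k' on the specific reactive area A across particle sizes.

    ``series`` rows are (A in cm^2 mmol^-1, k_prime, k_prime_sd).  With
    ``weighted`` the rows are weighted by 1 / sd^2 (rows with zero or
    missing sd make the weighted fit unavailable).
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InsufficientDataError(
            "need k' at >= 3 particle sizes to fit the slope"
        )
    A, kp = arr[:, 0], arr[:, 1]
    if np.ptp(A) == 0:
        raise DegenerateDesignError("reactive areas do not vary across sizes")
    if not weighted:
        slope, slope_sd, intercept, _, r2 = _ols_line(A, kp)
        return SlopeFit(slope, slope_sd, r2, intercept, arr.shape[0], weighted=False)

    sd = arr[:, 2]
    if np.any(~(sd > 0)):
        raise ValueError("weighted fit requires strictly positive k' SDs")
    w = 1.0 / sd**2
    X = np.column_stack([np.ones_like(A), A])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], kp * sw, rcond=None)
    resid = kp - X @ beta
    dof = arr.shape[0] - 2
    # weighted residual variance scales the normal-equation covariance
    s2 = float(w @ resid**2) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv((X * w[:, None]).T @ X)
    ybar = float(w @ kp) / float(w.sum())
    ss_tot = float(w @ (kp - ybar) ** 2)
    r2 = 1.0 - float(w @ resid**2) / ss_tot if ss_tot > 0 else 1.0
    return SlopeFit(
        slope=float(beta[1]),
        slope_sd=math.sqrt(max(cov[1, 1], 0.0)),
        r_squared=r2,
        intercept=float(beta[0]),
        n_points=arr.shape[0],
        weighted=True,
    )
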