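"""Initial-rate and normalized-rate extraction against closed-form OLS."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanosorb import (
    AdsorptionTrace,
    fit_kprime_vs_area,
    generate_trace,
    initial_rate,
    normalized_rate,
)
from nanosorb.rates import DegenerateDesignError, InsufficientDataError

R = 1.5e-6  # cm


def ols_slope_se(x, y):
    """Independent closed-form OLS slope and its standard error."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    resid = y - ybar - slope * (x - xbar)
    dof = x.size - 2
    se = np.sqrt(np.sum(resid**2) / dof / sxx) if dof > 0 else 0.0
    return slope, se


def linear_trace(slope, intercept=30.0, t_end=100.0, conc=1.0):
    t = np.arange(0.0, t_end + 0.5, 1.0)
    return AdsorptionTrace(
        times=t, peak_heights=intercept - slope * t, concentration_Cnp=conc, radius_R=R
    )


class TestInitialRate:
    def test_flat_trace_has_zero_rate(self):
        res = initial_rate(linear_trace(0.0))
        assert res.V == 0.0 and res.V_sd == 0.0

    def test_exact_line_recovered_without_uncertainty(self):
        res = initial_rate(linear_trace(0.1))
        assert res.V == pytest.approx(0.1, abs=1e-12)
        assert res.V_sd == pytest.approx(0.0, abs=1e-10)
        assert res.n_points == 51

    def test_noisy_trace_matches_independent_ols(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 51.0)
        y = 30.0 - 0.08 * t + rng.normal(0.0, 0.05, t.size)
        trace = AdsorptionTrace(times=t, peak_heights=y, concentration_Cnp=1.0, radius_R=R)
        res = initial_rate(trace)
        slope, se = ols_slope_se(t, y)
        assert res.V == pytest.approx(-slope, rel=1e-12)
        assert res.V_sd == pytest.approx(se, rel=1e-9)
        assert abs(res.V - 0.08) < 3 * res.V_sd

    def test_window_restricts_the_fit(self):
        # curvature outside the window must not leak into the slope
        t = np.arange(0.0, 201.0)
        y = np.where(t <= 50, 30.0 - 0.1 * t, 25.0 - 0.001 * (t - 50))
        trace = AdsorptionTrace(times=t, peak_heights=y, concentration_Cnp=1.0, radius_R=R)
        assert initial_rate(trace, window=(0, 50)).V == pytest.approx(0.1, abs=1e-12)

    def test_offset_invariance_and_time_reversal_sign_flip(self):
        trace = linear_trace(0.05)
        shifted = AdsorptionTrace(
            times=trace.times,
            peak_heights=trace.peak_heights + 7.0,
            concentration_Cnp=1.0,
            radius_R=R,
        )
        assert initial_rate(shifted).V == pytest.approx(initial_rate(trace).V)
        reversed_heights = trace.peak_heights[::-1]
        rev = AdsorptionTrace(
            times=trace.times, peak_heights=reversed_heights,
            concentration_Cnp=1.0, radius_R=R,
        )
        assert initial_rate(rev, window=(0, 100)).V == pytest.approx(
            -initial_rate(trace, window=(0, 100)).V
        )

    def test_errors(self):
        trace = linear_trace(0.1)
        with pytest.raises(InsufficientDataError):
            initial_rate(trace, window=(200.0, 250.0))
        with pytest.raises(ValueError):
            initial_rate(trace, window=(50.0, 0.0))
        with pytest.raises(ValueError):
            AdsorptionTrace(
                times=np.array([0.0, 2.0, 1.0]),
                peak_heights=np.zeros(3),
                concentration_Cnp=1.0,
                radius_R=R,
            )


class TestNormalizedRate:
    def test_exact_line_through_origin(self):
        nr = normalized_rate([(0, 0.0), (1, 0.5), (2, 1.0)], R)
        assert nr.k_prime == pytest.approx(0.5)
        assert nr.intercept == pytest.approx(0.0, abs=1e-12)
        assert nr.r_squared == pytest.approx(1.0)
        assert nr.n_concentrations == 3

    def test_constant_rates_give_zero_slope(self):
        nr = normalized_rate([(0, 0.3), (2, 0.3), (4, 0.3)], R)
        assert nr.k_prime == pytest.approx(0.0, abs=1e-15)

    def test_seeded_recovery_matches_oracle(self):
        rng = np.random.default_rng(7)
        conc = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        true_kp = 0.05
        V = true_kp * conc + rng.normal(0.0, 0.01, conc.size)
        nr = normalized_rate(list(zip(conc, V)), R)
        slope, se = ols_slope_se(conc, V)
        assert nr.k_prime == pytest.approx(slope, rel=1e-12)
        assert nr.k_prime_sd == pytest.approx(se, rel=1e-9)
        assert abs(nr.k_prime - true_kp) < 3 * nr.k_prime_sd

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None)
    def test_row_order_invariance(self, rnd):
        rows = [(0.0, 0.01), (2.0, 0.11), (4.0, 0.19), (6.0, 0.32), (8.0, 0.38)]
        shuffled = rows[:]
        rnd.shuffle(shuffled)
        a, b = normalized_rate(rows, R), normalized_rate(shuffled, R)
        assert a.k_prime == pytest.approx(b.k_prime, rel=1e-12)
        assert a.k_prime_sd == pytest.approx(b.k_prime_sd, rel=1e-12)

    def test_coverage_of_two_se_interval(self):
        """+/- 2 SE covers the true slope in >= 90% of seeded repetitions."""
        conc = np.arange(0.0, 13.0)  # enough df that +/-2 SE ~ 93% nominal
        true_kp = 0.05
        hits = 0
        n_rep = 200
        rng = np.random.default_rng(2024)
        for _ in range(n_rep):
            V = true_kp * conc + rng.normal(0.0, 0.02, conc.size)
            nr = normalized_rate(list(zip(conc, V)), R)
            if abs(nr.k_prime - true_kp) <= 2 * nr.k_prime_sd:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            normalized_rate([(0, 0.0), (1, 0.5)], R)
        with pytest.raises(DegenerateDesignError):
            normalized_rate([(3.0, 0.1), (3.0, 0.2), (3.0, 0.3)], R)


class TestSlopeVsAreaFit:
    AREAS = np.array([3.6e4, 7.3e3, 2.8e3, 6.5e2, 3.2e2, 1.8e2])

    def test_exact_proportionality(self):
        s_true = 1.36e-5
        series = [(A, s_true * A, 0.0) for A in self.AREAS]
        fit = fit_kprime_vs_area(series)
        assert fit.slope == pytest.approx(s_true, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_within_three_se(self):
        rng = np.random.default_rng(11)
        s_true = 1.36e-5
        kp = s_true * self.AREAS * (1 + rng.normal(0.0, 0.02, self.AREAS.size))
        series = [(A, k, 0.0) for A, k in zip(self.AREAS, kp)]
        fit = fit_kprime_vs_area(series)
        slope, se = ols_slope_se(self.AREAS, kp)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.slope_sd == pytest.approx(se, rel=1e-9)
        assert abs(fit.slope - s_true) < 3 * fit.slope_sd

    def test_weighted_fit_reduces_to_ols_under_equal_weights(self):
        rng = np.random.default_rng(3)
        kp = 1.0e-5 * self.AREAS + rng.normal(0, 1e-3, self.AREAS.size)
        series = [(A, k, 0.5) for A, k in zip(self.AREAS, kp)]
        w = fit_kprime_vs_area(series, weighted=True)
        u = fit_kprime_vs_area(series, weighted=False)
        assert w.slope == pytest.approx(u.slope, rel=1e-9)
        assert w.slope_sd == pytest.approx(u.slope_sd, rel=1e-6)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_kprime_vs_area([(3.6e4, 0.5, 0.0)])
        with pytest.raises(InsufficientDataError):
            fit_kprime_vs_area([(3.6e4, 0.5, 0.0), (7.3e3, 0.1, 0.0)])


class TestSyntheticTraceExtraction:
    def test_generated_noise_free_trace_yields_exact_initial_rate(self):
        k_het = 4.22e-4
        trace = generate_trace(R=1.5e-6, C=0.5, k_het=k_het, noise_sd=0.0)
        from nanosorb import kprime_from_rate_constant

        expected_V = kprime_from_rate_constant(k_het, 1.5e-6) * 0.5
        assert initial_rate(trace).V == pytest.approx(expected_V, rel=1e-12)
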