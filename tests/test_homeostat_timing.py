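"""Steady-state homeostat, timing BMSE closed forms, boundary hypothesis."""

import math

import numpy as np
import pytest

from bayescast import (
    BivariateTimingPrior,
    HomeostatParams,
    NoiseSpec,
    TimingSchedule,
    UnivariateTimingPrior,
    boundary_hypothesis_search,
    linear_coeffs,
    optimal_mean_time,
    optimal_times_bivariate,
    steady_state_s0,
    timing_bmse_bivariate,
    timing_bmse_from_summaries,
    timing_bmse_univariate,
    timing_feasibility,
    wake_curve,
)

FIG9 = HomeostatParams(tau_r=18.2, tau_d=4.2, T=16.0)


def recursion_fixed_point(params: HomeostatParams, dt: float = 0.5,
                          tol: float = 1e-13) -> float:
    """Independent oracle: iterate the discrete wake/sleep recursion to its
    fixed point over repeated 24 h cycles (exact for exponential dynamics).

    The nominal step dt is adjusted per phase so that it divides the wake
    and sleep spans exactly; the dynamics are step-size invariant.
    """
    n_wake = max(1, round(params.T / dt))
    sleep_span = 24.0 - params.T
    n_sleep = max(1, round(sleep_span / dt)) if sleep_span > 0 else 0
    rise = math.exp(-params.T / n_wake / params.tau_r)
    fall = math.exp(-sleep_span / n_sleep / params.tau_d) if n_sleep else 1.0
    s = 0.5
    for _ in range(100_000):
        prev = s
        for _ in range(n_wake):
            s = 1.0 - rise * (1.0 - s)
        for _ in range(n_sleep):
            s = fall * s
        if abs(s - prev) < tol:
            return s
    raise RuntimeError("fixed point did not converge")


class TestSteadyState:
    def test_no_sleep_pins_pressure_at_ceiling(self):
        assert steady_state_s0(HomeostatParams(18.2, 4.2, 24.0)) == pytest.approx(1.0)

    def test_reference_schedule_matches_recursion_oracle(self):
        s0 = steady_state_s0(FIG9)
        assert s0 == pytest.approx(0.0928, abs=5e-5)
        assert s0 == pytest.approx(recursion_fixed_point(FIG9, 0.5), abs=1e-12)
        # exact exponential dynamics: oracle invariant to step size
        assert recursion_fixed_point(FIG9, 0.05) == pytest.approx(
            recursion_fixed_point(FIG9, 0.5), abs=1e-11)

    def test_closed_form_equals_fixed_point_on_random_draws(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            p = HomeostatParams(rng.uniform(1, 30), rng.uniform(1, 30),
                                rng.uniform(0.5, 23.5))
            s_closed = steady_state_s0(p)
            # exact dynamics: one wake pass + one sleep pass per cycle
            s = 0.5
            for _ in range(100_000):
                prev = s
                s = 1.0 - math.exp(-p.T / p.tau_r) * (1.0 - s)
                s = math.exp(-(24.0 - p.T) / p.tau_d) * s
                if abs(s - prev) < 1e-15:
                    break
            assert s_closed == pytest.approx(s, abs=1e-10)
            assert 0.0 < s_closed < 1.0


class TestLinearApproximation:
    def test_chord_interpolates_wake_curve_endpoints(self):
        alpha, beta = linear_coeffs(FIG9)
        assert alpha == pytest.approx(steady_state_s0(FIG9), rel=1e-14)
        end = float(wake_curve(FIG9, FIG9.T))
        assert alpha + beta * FIG9.T == pytest.approx(end, rel=1e-12)

    def test_slope_matches_recursion_endpoint(self):
        s0 = recursion_fixed_point(FIG9)
        s_end = 1.0 - (1.0 - s0) * math.exp(-FIG9.T / FIG9.tau_r)
        _, beta = linear_coeffs(FIG9)
        assert beta == pytest.approx((s_end - s0) / FIG9.T, abs=1e-12)

    def test_flat_homeostat_limit(self):
        p = HomeostatParams(1e9, 4.2, 16.0)
        _, beta = linear_coeffs(p)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_gap_is_largest_away_from_endpoints(self):
        # approximation exact at t = 0 and T; interior gap bounded by the
        # curvature midpoint value
        alpha, beta = linear_coeffs(FIG9)
        t = np.linspace(0, FIG9.T, 401)
        gap = np.abs(wake_curve(FIG9, t) - (alpha + beta * t))
        assert gap[0] == pytest.approx(0.0, abs=1e-12)
        assert gap[-1] == pytest.approx(0.0, abs=1e-12)
        assert gap.max() > gap[1] and gap.max() > gap[-2]


class TestUnivariateTimingBmse:
    prior = UnivariateTimingPrior(delta_alpha=0.4, delta_beta=0.05)

    def test_depends_only_on_time_summaries(self):
        rng = np.random.default_rng(5)
        times = rng.uniform(0, 16, 7)
        a = TimingSchedule(times, t_star=18.0)
        b = TimingSchedule(rng.permutation(times), t_star=18.0)
        assert timing_bmse_univariate(a, self.prior, 0.3) == pytest.approx(
            timing_bmse_univariate(b, self.prior, 0.3), rel=1e-12)
        # different times, same (m, t_bar, s^2)
        mean, sd = times.mean(), times.std()
        sym = mean + sd * np.array([1, -1, 1, -1, 1, -1, 1]) * 1.0
        sym = (sym - sym.mean()) * (sd / sym.std()) + mean
        c = TimingSchedule(sym, t_star=18.0)
        assert timing_bmse_univariate(c, self.prior, 0.3) == pytest.approx(
            timing_bmse_univariate(a, self.prior, 0.3), rel=1e-12)

    def test_matches_matrix_engine(self):
        from bayescast import (DesignMatrix, posterior_covariance,
                               prediction_bmse)
        rng = np.random.default_rng(17)
        noise = NoiseSpec({1: 0.3})
        for _ in range(20):
            m = int(rng.integers(1, 10))
            times = rng.uniform(0, 16, m)
            t_star = rng.uniform(0, 24)
            sched = TimingSchedule(times, t_star=t_star)
            closed = timing_bmse_univariate(sched, self.prior, 0.3)
            design = DesignMatrix(np.column_stack([np.ones(m), times]),
                                  np.ones(m, dtype=int))
            cov = posterior_covariance(self.prior.to_gaussian_prior(), design, noise)
            engine = prediction_bmse(np.array([1.0, t_star]), cov)
            assert closed == pytest.approx(engine, rel=1e-10)

    def test_spreading_measurement_times_helps(self):
        vals = [timing_bmse_from_summaries(5, 8.0, s2, 18.0, self.prior, 0.3)
                for s2 in np.linspace(0.0, 400.0, 50)]
        assert np.all(np.diff(vals) < 0)

    def test_simultaneous_measurements_allowed(self):
        v = timing_bmse_from_summaries(4, 10.0, 0.0, 12.0, self.prior, 0.3)
        assert v > 0


class TestOptimalMeanTime:
    def test_vague_intercept_prior_centres_on_prediction_time(self):
        prior = UnivariateTimingPrior(1e6, 0.05)
        assert optimal_mean_time(18.0, prior, 0.3, 4) == pytest.approx(18.0, rel=1e-9)

    def test_equal_prior_and_error_variance_offsets_by_tstar_over_m(self):
        prior = UnivariateTimingPrior(0.3, 0.05)
        assert optimal_mean_time(18.0, prior, 0.3, 1) == pytest.approx(36.0)

    def test_dense_sweep_attains_minimum_at_formula_value(self):
        prior = UnivariateTimingPrior(0.4, 0.05)
        m, s2, t_star, sigma = 5, 2.0, 10.0, 0.3
        t_min = optimal_mean_time(t_star, prior, sigma, m)
        grid = np.linspace(t_min - 8, t_min + 8, 30_001)
        vals = [timing_bmse_from_summaries(m, tb, s2, t_star, prior, sigma)
                for tb in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(t_min, abs=1e-3)

    def test_feasibility_labels(self):
        assert timing_feasibility(8.0, 16.0) == "interior"
        assert timing_feasibility(16.0, 16.0) == "boundary"
        assert timing_feasibility(20.0, 16.0) == "boundary"

    def test_single_measurement_boundary_case_optimal_at_T(self):
        # when the unconstrained optimum falls beyond T, measuring at T
        # beats every feasible single measurement time
        prior = UnivariateTimingPrior(0.2, 0.05)
        sigma, T = 0.5, 16.0
        t_star = 15.0
        assert optimal_mean_time(t_star, prior, sigma, 1) > T
        at_T = timing_bmse_from_summaries(1, T, 0.0, t_star, prior, sigma)
        for t in np.linspace(0, T, 2001):
            assert at_T <= timing_bmse_from_summaries(1, t, 0.0, t_star, prior, sigma) + 1e-15


class TestBivariateTiming:
    prior = BivariateTimingPrior(0.4, 0.5, 0.6, 0.05, 0.04, 0.3)
    noise = NoiseSpec({1: 0.3, 2: 0.2})

    def test_reduces_to_univariate_without_secondary_data(self):
        rng = np.random.default_rng(29)
        times = rng.uniform(0, 16, 5)
        sched = TimingSchedule(times, t_star=18.0)
        uni = UnivariateTimingPrior(0.4, 0.05)
        assert timing_bmse_bivariate(sched, self.prior, self.noise) == pytest.approx(
            timing_bmse_univariate(sched, uni, 0.3), rel=1e-10)

    def test_uncorrelated_secondary_is_inert(self):
        prior0 = BivariateTimingPrior(0.4, 0.5, 0.0, 0.05, 0.04, 0.0)
        rng = np.random.default_rng(31)
        t1 = rng.uniform(0, 16, 4)
        a = TimingSchedule(t1, rng.uniform(0, 16, 6), t_star=18.0)
        b = TimingSchedule(t1, rng.uniform(0, 16, 6), t_star=18.0)
        assert timing_bmse_bivariate(a, prior0, self.noise) == pytest.approx(
            timing_bmse_bivariate(b, prior0, self.noise), rel=1e-12)

    def test_equal_summary_schedules_give_equal_bmse(self):
        rng = np.random.default_rng(37)
        for _ in range(10):
            m1, m2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            t1 = rng.uniform(0, 16, m1)
            t2 = rng.uniform(0, 16, m2)

            def match(t):  # different times, same mean and 1/m variance
                flipped = 2 * t.mean() - t
                return flipped

            a = TimingSchedule(t1, t2, t_star=18.0)
            b = TimingSchedule(match(t1), match(t2), t_star=18.0)
            assert timing_bmse_bivariate(a, self.prior, self.noise) == pytest.approx(
                timing_bmse_bivariate(b, self.prior, self.noise), rel=1e-10)

    def test_optimal_means_match_grid_search(self):
        rng = np.random.default_rng(41)
        for _ in range(3):
            m1, m2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            t_star = rng.uniform(2, 10)
            t1_min, t2_min = optimal_times_bivariate(t_star, self.prior,
                                                     self.noise, m1, m2)
            assert t2_min == 0.0
            assert t1_min >= t_star
            g1 = np.linspace(t1_min - 6, t1_min + 6, 121)
            g2 = np.linspace(-6, 6, 61)
            best = None
            for a in g1:
                for b in g2:
                    sched = TimingSchedule(np.full(m1, a), np.full(m2, b), t_star)
                    v = timing_bmse_bivariate(sched, self.prior, self.noise)
                    if best is None or v < best[0]:
                        best = (v, a, b)
            assert best[1] == pytest.approx(t1_min, abs=0.11)
            assert best[2] == pytest.approx(0.0, abs=0.11)

    def test_m2_limit_recovers_univariate_optimum(self):
        uni = UnivariateTimingPrior(0.4, 0.05)
        expected = optimal_mean_time(6.0, uni, 0.3, 3)
        got, _ = optimal_times_bivariate(6.0, self.prior, self.noise, 3, 0)
        assert got == pytest.approx(expected, rel=1e-12)
        # rho = 0 decouples the responses for any m2
        prior0 = BivariateTimingPrior(0.4, 0.5, 0.0, 0.05, 0.04, 0.3)
        got0, _ = optimal_times_bivariate(6.0, prior0, self.noise, 3, 7)
        assert got0 == pytest.approx(expected, rel=1e-12)


class TestBoundaryHypothesisSearch:
    def test_empty_search(self):
        rep = boundary_hypothesis_search(0, seed=1)
        assert rep["counterexamples"] == 0 and rep["examples"] == []

    def test_univariate_hypothesis_survives_seeded_search(self):
        rep = boundary_hypothesis_search(20_000, seed=9, mode="univariate")
        assert rep["counterexamples"] == 0

    def test_bivariate_high_slope_correlation_breaks_hypothesis(self):
        rep = boundary_hypothesis_search(10_000, seed=9, mode="bivariate",
                                         ranges={"omega": (0.999, 0.999)})
        assert rep["counterexamples"] >= 1
        ex = rep["examples"][0]
        assert ex["bmse_candidate"] < ex["bmse_hypothesis"]
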