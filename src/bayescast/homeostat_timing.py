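"""Measurement timing for a linearised sleep-homeostat model.

The homeostatic sleep-pressure process rises exponentially toward 1 during
wake (time constant tau_r) and decays toward 0 during sleep (tau_d).  On a
repeating 24 h schedule with T waking hours the pressure at wake onset
settles at the steady state

    S0 = exp(-(24-T)/tau_d) (1 - exp(-T/tau_r))
         / (1 - exp(-(24-T)/tau_d - T/tau_r)),

and over one wake period the curve is approximated by the chord through its
endpoints: intercept alpha = S0 and slope
beta = (1 - exp(-T/tau_r)) (1 - S0) / T.

With subject-specific (alpha, beta) given independent Gaussian priors, the
BMSE of predicting the expected response at time t* depends on the m
measurement times only through their mean t_bar and (1/m-normalised)
variance s^2:

    M = [1/db^2 + m s^2/sg^2 + m (t_bar - t*)^2/sg^2 + t*^2/da^2]
        / [(1/da^2 + m/sg^2)(1/db^2 + m(s^2 + t_bar^2)/sg^2) - (m t_bar/sg^2)^2]

(da = delta_alpha, db = delta_beta, sg = sigma).  For fixed s^2 the optimal
mean time is t_bar_min = t* (sg^2/m + da^2)/da^2, slightly after the
prediction time.  When t_bar_min >= T the unconstrained optimum is outside
the feasible window [0, T]; the working hypothesis (supported by a seeded
simulation search, and provable for m <= 2) is that all measurements should
then be taken at T.

The bivariate extension adds a correlated secondary response (intercept
correlation rho, slope correlation omega); its BMSE is evaluated through the
generic matrix engine, with a reconstructed closed form for the optimal
primary mean time used as a fast path and validated against grid search.
The all-at-the-boundary hypothesis fails in the bivariate case when omega is
very large (> 0.99) or T is small relative to the slope prior scales; the
search reproduces such counterexamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .linear_gaussian_core import (
    DesignMatrix,
    GaussianPrior,
    NoiseSpec,
    posterior_covariance,
    prediction_bmse,
)

__all__ = [
    "HomeostatParams",
    "UnivariateTimingPrior",
    "BivariateTimingPrior",
    "TimingSchedule",
    "steady_state_s0",
    "wake_curve",
    "linear_coeffs",
    "timing_bmse_univariate",
    "timing_bmse_from_summaries",
    "optimal_mean_time",
    "timing_feasibility",
    "timing_bmse_bivariate",
    "optimal_times_bivariate",
    "boundary_hypothesis_search",
]


@dataclass(frozen=True)
class HomeostatParams:
    """Two-process homeostat time constants and wake duration (24 h period)."""

    tau_r: float  # rise time constant during wake, h
    tau_d: float  # decay time constant during sleep, h
    T: float = 16.0  # wake duration, h

    def __post_init__(self) -> None:
        if not (self.tau_r > 0 and self.tau_d > 0):
            raise ValueError("time constants must be > 0")
        if not 0 < self.T <= 24:
            raise ValueError("wake duration must lie in (0, 24]")


@dataclass(frozen=True)
class UnivariateTimingPrior:
    """Independent Gaussian priors on intercept and slope."""

    delta_alpha: float
    delta_beta: float
    mu: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.delta_alpha > 0 and self.delta_beta > 0):
            raise ValueError("prior s.d.s must be > 0")

    def to_gaussian_prior(self) -> GaussianPrior:
        return GaussianPrior(
            np.asarray(self.mu, dtype=float),
            np.diag([self.delta_alpha**2, self.delta_beta**2]),
        )


@dataclass(frozen=True)
class BivariateTimingPrior:
    """Correlated intercept pair (rho) and slope pair (omega), blocks independent.

    Parameter order is (alpha1, alpha2, beta1, beta2).
    """

    delta_alpha1: float
    delta_alpha2: float
    rho: float
    delta_beta1: float
    delta_beta2: float
    omega: float
    mu: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.delta_alpha1, self.delta_alpha2, self.delta_beta1, self.delta_beta2) <= 0:
            raise ValueError("prior s.d.s must be > 0")
        if not (abs(self.rho) < 1 and abs(self.omega) < 1):
            raise ValueError("|rho| and |omega| must be < 1")

    def to_gaussian_prior(self) -> GaussianPrior:
        da1, da2, db1, db2 = (
            self.delta_alpha1,
            self.delta_alpha2,
            self.delta_beta1,
            self.delta_beta2,
        )
        cov = np.zeros((4, 4))
        cov[:2, :2] = [[da1**2, self.rho * da1 * da2], [self.rho * da1 * da2, da2**2]]
        cov[2:, 2:] = [
            [db1**2, self.omega * db1 * db2],
            [self.omega * db1 * db2, db2**2],
        ]
        return GaussianPrior(np.asarray(self.mu, dtype=float), cov)


@dataclass(frozen=True)
class TimingSchedule:
    """Measurement times per response type plus the prediction time t_star.

    Summary statistics use the population normalisation 1/m for the time
    variance; that convention is what makes the closed-form BMSE exact.
    """

    times1: np.ndarray
    times2: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_star: float = 0.0

    def __post_init__(self) -> None:
        t1 = np.atleast_1d(np.asarray(self.times1, dtype=float))
        t2 = np.atleast_1d(np.asarray(self.times2, dtype=float)) if np.size(self.times2) else np.empty(0)
        object.__setattr__(self, "times1", t1)
        object.__setattr__(self, "times2", t2)

    @property
    def m1(self) -> int:
        return self.times1.size

    @property
    def m2(self) -> int:
        return self.times2.size

    @property
    def t_bar1(self) -> float:
        return float(self.times1.mean())

    @property
    def s1_sq(self) -> float:
        return float(self.times1.var())  # ddof=0, i.e. 1/m

    @property
    def t_bar2(self) -> float:
        return float(self.times2.mean())

    @property
    def s2_sq(self) -> float:
        return float(self.times2.var())


def steady_state_s0(params: HomeostatParams) -> float:
    """Steady-state homeostatic pressure at wake onset on a repeating schedule."""
    T, tau_r, tau_d = params.T, params.tau_r, params.tau_d
    sleep = 24.0 - T
    num = math.exp(-sleep / tau_d) * (1.0 - math.exp(-T / tau_r))
    den = 1.0 - math.exp(-sleep / tau_d - T / tau_r)
    return num / den


def wake_curve(params: HomeostatParams, t: np.ndarray) -> np.ndarray:
    """Exact exponential pressure t hours into a steady-state wake period."""
    s0 = steady_state_s0(params)
    return 1.0 - (1.0 - s0) * np.exp(-np.asarray(t, dtype=float) / params.tau_r)


def linear_coeffs(params: HomeostatParams) -> tuple[float, float]:
    """Chord (intercept, slope) interpolating the wake curve at t = 0 and t = T."""
    s0 = steady_state_s0(params)
    beta = (1.0 - math.exp(-params.T / params.tau_r)) * (1.0 - s0) / params.T
    return s0, beta


def timing_bmse_from_summaries(
    m: float,
    t_bar: float,
    s_sq: float,
    t_star: float,
    prior: UnivariateTimingPrior,
    sigma: float,
) -> float:
    """Closed-form univariate timing BMSE in terms of (m, t_bar, s^2, t*)."""
    if m < 1:
        raise ValueError("need at least one measurement")
    da2 = prior.delta_alpha**2
    db2 = prior.delta_beta**2
    sg2 = sigma**2
    num = 1.0 / db2 + m * s_sq / sg2 + m * (t_bar - t_star) ** 2 / sg2 + t_star**2 / da2
    den = (1.0 / da2 + m / sg2) * (1.0 / db2 + m * (s_sq + t_bar**2) / sg2) - (
        m * t_bar / sg2
    ) ** 2
    return num / den


def timing_bmse_univariate(
    schedule: TimingSchedule, prior: UnivariateTimingPrior, sigma: float
) -> float:
    """Univariate timing BMSE; depends on the times only through (t_bar, s^2)."""
    return timing_bmse_from_summaries(
        schedule.m1, schedule.t_bar1, schedule.s1_sq, schedule.t_star, prior, sigma
    )


def optimal_mean_time(
    t_star: float, prior: UnivariateTimingPrior, sigma: float, m: int
) -> float:
    """Mean measurement time minimising the BMSE at fixed s^2.

    ``t_bar_min = t* (sigma^2/m + delta_alpha^2) / delta_alpha^2`` — always at
    or after the prediction time, approaching it as the intercept prior
    tightens toward certainty being irrelevant (delta_alpha -> inf).
    """
    if m < 1:
        raise ValueError("need at least one measurement")
    da2 = prior.delta_alpha**2
    if da2 == 0:
        raise ValueError("delta_alpha must be > 0")
    return t_star * (sigma**2 / m + da2) / da2


def timing_feasibility(t_bar_min: float, T: float) -> str:
    """'interior' if the unconstrained optimum fits in [0, T], else 'boundary'.

    In the boundary case the recommended schedule places every measurement at
    T (the simulation-backed hypothesis; exact for m <= 2).
    """
    return "interior" if t_bar_min < T else "boundary"


def _bivariate_design(schedule: TimingSchedule) -> DesignMatrix:
    m1, m2 = schedule.m1, schedule.m2
    rows = np.zeros((m1 + m2, 4))
    rows[:m1, 0] = 1.0
    rows[:m1, 2] = schedule.times1
    rows[m1:, 1] = 1.0
    rows[m1:, 3] = schedule.times2
    types = np.array([1] * m1 + [2] * m2, dtype=int)
    return DesignMatrix(rows, types)


def timing_bmse_bivariate(
    schedule: TimingSchedule, prior: BivariateTimingPrior, noise: NoiseSpec
) -> float:
    """Primary-prediction BMSE for the four-parameter bivariate timing model.

    Evaluated through the matrix engine with functional h = (1, 0, t*, 0);
    with no secondary measurements it reduces to the univariate closed form.
    """
    if schedule.m1 < 1 and schedule.m2 < 1:
        raise ValueError("need at least one measurement of either type")
    cov = posterior_covariance(prior.to_gaussian_prior(), _bivariate_design(schedule), noise)
    h = np.array([1.0, 0.0, schedule.t_star, 0.0])
    return prediction_bmse(h, cov)


def optimal_times_bivariate(
    t_star: float,
    prior: BivariateTimingPrior,
    noise: NoiseSpec,
    m1: int,
    m2: float,
) -> tuple[float, float]:
    """Optimal (mean primary time, mean secondary time) at fixed spreads.

    The secondary mean is 0 (secondary data anchor the intercepts, which are
    most informative about the primary intercept at time zero); the primary
    mean is the univariate rule with the intercept prior shrunk by the
    secondary information:

        t_bar1_min = t* [da1^2((1-rho^2) da2^2 + s2^2/m2)
                         + (s1^2/m1)(da2^2 + s2^2/m2)]
                     / [da1^2((1-rho^2) da2^2 + s2^2/m2)].

    As m2 -> 0 this recovers the univariate optimum; with rho = 0 the
    secondary counts drop out entirely.
    """
    if m1 < 1:
        raise ValueError("need at least one primary measurement")
    da1sq = prior.delta_alpha1**2
    da2sq = prior.delta_alpha2**2
    s1sq = noise.sigma(1) ** 2
    if m2 == 0:
        uni = UnivariateTimingPrior(prior.delta_alpha1, prior.delta_beta1)
        return optimal_mean_time(t_star, uni, noise.sigma(1), m1), 0.0
    s2sq_over_m2 = noise.sigma(2) ** 2 / m2
    shrunk = da1sq * ((1.0 - prior.rho**2) * da2sq + s2sq_over_m2)
    t_bar1 = t_star * (shrunk + (s1sq / m1) * (da2sq + s2sq_over_m2)) / shrunk
    return t_bar1, 0.0


# ---------------------------------------------------------------------------
# boundary-hypothesis simulation search
# ---------------------------------------------------------------------------

_DEFAULT_RANGES = {
    "delta": (0.001, 1.0),
    "sigma": (0.001, 1.0),
    "m_max": 100,
    "rho": (-0.99, 0.99),
    "omega": (-0.99, 0.99),
}


def _row_stats(times: np.ndarray, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and 1/m variance of the first m[i] entries of each row."""
    csum = np.cumsum(times, axis=1)
    csq = np.cumsum(times**2, axis=1)
    idx = np.arange(times.shape[0])
    tot = csum[idx, m - 1]
    totsq = csq[idx, m - 1]
    t_bar = tot / m
    s_sq = np.maximum(totsq / m - t_bar**2, 0.0)
    return t_bar, s_sq


def boundary_hypothesis_search(
    n_draws: int,
    seed: int,
    mode: str = "univariate",
    T: float = 16.0,
    ranges: dict | None = None,
    max_examples: int = 20,
) -> dict:
    """Random search for counterexamples to the all-data-at-T hypothesis.

    Draws prior/noise scales uniformly (default U(0.001, 1)), measurement
    counts uniformly on {1..m_max}, and a prediction time in the range that
    forces the unconstrained optimum outside [0, T] (the boundary case).  For
    each draw the BMSE of the hypothesised design (univariate: everything at
    T; bivariate: primary at T, secondary at 0) is compared against a random
    feasible schedule; a strictly smaller random-schedule BMSE is a
    counterexample.

    Returns a dict with the draw count, counterexample count and up to
    ``max_examples`` offending parameter sets.  Deterministic given the seed.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if mode not in ("univariate", "bivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    r = dict(_DEFAULT_RANGES)
    r.update(ranges or {})
    report = {"mode": mode, "n_draws": n_draws, "T": T, "counterexamples": 0, "examples": []}
    if n_draws == 0:
        return report

    if mode == "univariate":
        chunk = 20_000
        done = 0
        while done < n_draws:
            n = min(chunk, n_draws - done)
            da = rng.uniform(*r["delta"], n)
            db = rng.uniform(*r["delta"], n)
            sg = rng.uniform(*r["sigma"], n)
            m = rng.integers(1, r["m_max"] + 1, n)
            # force the boundary case: t_bar_min(t*) >= T
            lo = T * da**2 / (sg**2 / m + da**2)
            t_star = rng.uniform(lo, T)
            times = rng.uniform(0.0, T, size=(n, r["m_max"]))
            t_bar, s_sq = _row_stats(times, m)

            def _bmse(tb, ss):
                da2, db2, sg2 = da**2, db**2, sg**2
                num = 1.0 / db2 + m * ss / sg2 + m * (tb - t_star) ** 2 / sg2 + t_star**2 / da2
                den = (1.0 / da2 + m / sg2) * (1.0 / db2 + m * (ss + tb**2) / sg2) - (
                    m * tb / sg2
                ) ** 2
                return num / den

            m_hyp = _bmse(np.full(n, T), np.zeros(n))
            m_cand = _bmse(t_bar, s_sq)
            bad = m_cand < m_hyp * (1.0 - 1e-12)
            report["counterexamples"] += int(bad.sum())
            for i in np.flatnonzero(bad):
                if len(report["examples"]) >= max_examples:
                    break
                report["examples"].append(
                    {
                        "delta_alpha": float(da[i]),
                        "delta_beta": float(db[i]),
                        "sigma": float(sg[i]),
                        "m": int(m[i]),
                        "t_star": float(t_star[i]),
                        "bmse_hypothesis": float(m_hyp[i]),
                        "bmse_candidate": float(m_cand[i]),
                    }
                )
            done += n
        return report

    # bivariate mode
    for _ in range(n_draws):
        da1, da2_, db1, db2_ = rng.uniform(*r["delta"], 4)
        sg1, sg2 = rng.uniform(*r["sigma"], 2)
        rho = rng.uniform(*r["rho"])
        omega = rng.uniform(*r["omega"])
        m1 = int(rng.integers(1, r["m_max"] + 1))
        m2 = int(rng.integers(1, r["m_max"] + 1))
        prior = BivariateTimingPrior(da1, da2_, rho, db1, db2_, omega)
        noise = NoiseSpec({1: sg1, 2: sg2})
        # force the boundary case through the reconstructed t_bar1_min rule
        t_bar1_min_at = optimal_times_bivariate(1.0, prior, noise, m1, m2)[0]
        t_star = rng.uniform(T / t_bar1_min_at, T)
        hyp = TimingSchedule(np.full(m1, T), np.zeros(m2), t_star)
        cand = TimingSchedule(rng.uniform(0, T, m1), rng.uniform(0, T, m2), t_star)
        m_hyp = timing_bmse_bivariate(hyp, prior, noise)
        m_cand = timing_bmse_bivariate(cand, prior, noise)
        if m_cand < m_hyp * (1.0 - 1e-12):
            report["counterexamples"] += 1
            if len(report["examples"]) < max_examples:
                report["examples"].append(
                    {
                        "delta_alpha1": da1,
                        "delta_alpha2": da2_,
                        "delta_beta1": db1,
                        "delta_beta2": db2_,
                        "sigma1": sg1,
                        "sigma2": sg2,
                        "rho": rho,
                        "omega": omega,
                        "m1": m1,
                        "m2": m2,
                        "t_star": t_star,
                        "bmse_hypothesis": m_hyp,
                        "bmse_candidate": m_cand,
                    }
                )
    return report
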