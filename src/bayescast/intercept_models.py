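"""Closed-form MMSE shrinkage and BMSE for random-intercept models.

Univariate model: a subject's responses are ``y_j = theta + eps_j`` with
``theta ~ N(mu, delta^2)`` across subjects and ``eps_j ~ N(0, sigma^2)``.
The MMSE estimate shrinks the subject's sample mean toward the population
mean with weight ``upsilon = delta^2 / (delta^2 + sigma^2/m)``, and its BMSE
is ``(sigma^2/m) * delta^2 / (delta^2 + sigma^2/m)``.

Bivariate model: two response types share a subject through correlated
intercepts ``(theta_1, theta_2)`` with between-subjects correlation rho.
Secondary observations inform the primary intercept only through rho; the
primary-prediction BMSE collapses to

    M(theta_1_hat) = (m1/sigma1^2 + 1/delta1^2 + lambda(m2))^{-1},
    lambda(m2) = rho^2 (delta2^2/delta1^2) / (delta2^2 (1-rho^2) + sigma2^2/m2),

where lambda quantifies the information transferred per secondary sample
size m2.  Counts may be non-negative reals (the design optimiser works with
continuous "nights") or integers when actual designs are built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .linear_gaussian_core import (
    DesignMatrix,
    GaussianPrior,
    NoiseSpec,
    mmse_estimate,
)

__all__ = [
    "UnivariateInterceptPrior",
    "BivariateInterceptPrior",
    "DesignCounts",
    "univariate_shrinkage",
    "univariate_bmse",
    "build_bivariate_design",
    "lambda_secondary",
    "bivariate_bmse_primary",
    "forecast_univariate",
    "forecast_bivariate",
]


@dataclass(frozen=True)
class UnivariateInterceptPrior:
    """Population prior: intercept mean ``mu`` and between-subjects s.d. ``delta``."""

    mu: float
    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")

    def to_gaussian_prior(self) -> GaussianPrior:
        return GaussianPrior(np.array([self.mu]), np.array([[self.delta**2]]))


@dataclass(frozen=True)
class BivariateInterceptPrior:
    """Correlated primary/secondary intercept prior.

    ``rho`` is the between-subjects correlation between the primary and
    secondary subject means — the only channel through which secondary data
    inform primary predictions in this model.
    """

    mu1: float
    mu2: float
    delta1: float
    delta2: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.delta1 > 0 and self.delta2 > 0):
            raise ValueError("between-subjects s.d.s must be > 0")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")

    def to_gaussian_prior(self) -> GaussianPrior:
        off = self.rho * self.delta1 * self.delta2
        cov = np.array([[self.delta1**2, off], [off, self.delta2**2]])
        return GaussianPrior(np.array([self.mu1, self.mu2]), cov)


@dataclass(frozen=True)
class DesignCounts:
    """Numbers of primary (m1) and secondary (m2) observations.

    Continuous values are allowed inside design computations; integer values
    are required to build an actual design matrix.
    """

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if self.m1 < 0 or self.m2 < 0:
            raise ValueError(f"counts must be >= 0, got ({self.m1}, {self.m2})")


def univariate_shrinkage(
    prior: UnivariateInterceptPrior, sigma: float, y: np.ndarray
) -> tuple[float, float]:
    """MMSE intercept estimate and its shrinkage weight.

    Returns ``(theta_hat, upsilon)`` where ``theta_hat = upsilon*ybar +
    (1-upsilon)*mu``.  With no data the estimate is the population mean and
    the weight is 0.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    y = np.atleast_1d(np.asarray(y, dtype=float))
    m = y.size
    if m == 0:
        return prior.mu, 0.0
    upsilon = prior.delta**2 / (prior.delta**2 + sigma**2 / m)
    theta_hat = upsilon * y.mean() + (1.0 - upsilon) * prior.mu
    return float(theta_hat), float(upsilon)


def univariate_bmse(prior: UnivariateInterceptPrior, sigma: float, m: float) -> float:
    """BMSE of the univariate MMSE estimate after m observations.

    Equals the posterior variance ``(sigma^2/m) delta^2 / (delta^2 +
    sigma^2/m)``; for m = 0 it is the prior variance ``delta^2``.  Strictly
    decreasing in m.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    if m < 0:
        raise ValueError("m must be >= 0")
    d2 = prior.delta**2
    if m == 0:
        return d2
    s2m = sigma**2 / m
    return s2m * d2 / (d2 + s2m)


def build_bivariate_design(counts: DesignCounts) -> DesignMatrix:
    """Stacked (m1+m2) x 2 design: rows (1,0) for primary, (0,1) for secondary."""
    m1, m2 = counts.m1, counts.m2
    if m1 != int(m1) or m2 != int(m2):
        raise ValueError("building a design matrix requires integer counts")
    m1, m2 = int(m1), int(m2)
    rows = np.zeros((m1 + m2, 2))
    rows[:m1, 0] = 1.0
    rows[m1:, 1] = 1.0
    types = np.array([1] * m1 + [2] * m2, dtype=int)
    return DesignMatrix(rows, types)


def lambda_secondary(
    prior: BivariateInterceptPrior, sigma2: float, m2: float
) -> float:
    """Information about the primary intercept per m2 secondary observations.

    ``lambda(m2) = rho^2 (delta2^2/delta1^2) / (delta2^2(1-rho^2) + sigma2^2/m2)``,
    defined by its continuous limit 0 at m2 = 0.  Nondecreasing in m2 with
    supremum ``rho^2 / (delta1^2 (1-rho^2))``.
    """
    if m2 < 0:
        raise ValueError("m2 must be >= 0")
    if m2 == 0 or prior.rho == 0.0:
        return 0.0
    num = prior.rho**2 * prior.delta2**2 / prior.delta1**2
    den = prior.delta2**2 * (1.0 - prior.rho**2) + sigma2**2 / m2
    return num / den


def bivariate_bmse_primary(
    prior: BivariateInterceptPrior, noise: NoiseSpec, counts: DesignCounts
) -> float:
    """BMSE of the primary-intercept MMSE estimate for counts (m1, m2).

    ``(m1/sigma1^2 + 1/delta1^2 + lambda(m2))^{-1}``; continuous counts are
    allowed.  Decreasing in both counts (strictly in m2 when rho != 0), with
    prior-only value delta1^2 and the m1=0, m2->inf floor delta1^2(1-rho^2).
    """
    s1 = noise.sigma(1)
    s2 = noise.sigma(2)
    lam = lambda_secondary(prior, s2, counts.m2)
    return 1.0 / (counts.m1 / s1**2 + 1.0 / prior.delta1**2 + lam)


def forecast_univariate(
    prior: UnivariateInterceptPrior,
    sigma: float,
    y: np.ndarray,
    level: float = 0.95,
):
    """Full posterior summary (estimate, BMSE, CI) for the univariate model.

    Thin wrapper over the matrix engine on the equivalent one-parameter
    design; agrees exactly with :func:`univariate_shrinkage`.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    design = DesignMatrix(np.ones((y.size, 1)), np.ones(y.size, dtype=int))
    return mmse_estimate(
        prior.to_gaussian_prior(),
        design,
        NoiseSpec({1: sigma}),
        y,
        h=np.array([1.0]),
        level=level,
    )


def forecast_bivariate(
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
    y1: np.ndarray,
    y2: np.ndarray,
    level: float = 0.95,
):
    """Posterior summary of the primary intercept from stacked observations."""
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    y2 = np.atleast_1d(np.asarray(y2, dtype=float))
    design = build_bivariate_design(DesignCounts(y1.size, y2.size))
    return mmse_estimate(
        prior.to_gaussian_prior(),
        design,
        noise,
        np.concatenate([y1, y2]),
        h=np.array([1.0, 0.0]),
        level=level,
    )
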