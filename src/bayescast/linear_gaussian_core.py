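"""Conjugate linear-Gaussian engine for Bayesian forecasting.

Every closed-form accuracy expression in this package (shrinkage weights,
bivariate-intercept BMSE, timing BMSE) is a special case of the posterior of a
Gaussian parameter vector ``theta ~ N(mu, C_theta)`` observed through a linear
design ``y = H theta + eps`` with independent Gaussian errors.  This module
implements that general posterior once, so the specialised closed forms can be
verified against it.

Notation
--------
mu, C_theta
    Prior (population) mean and between-subjects covariance of the
    subject-specific parameter vector.
H
    Design matrix mapping parameters to observations; each row carries a
    response-type index selecting the within-subjects error s.d.
sigma_r
    Within-subjects (measurement-error) standard deviation of response type r;
    errors are independent, so the error covariance is diagonal.

The posterior is ``N(theta_hat, Sigma)`` with precision
``Sigma^{-1} = C_theta^{-1} + H' C_eps^{-1} H`` and mean
``theta_hat = mu + Sigma H' C_eps^{-1} (y - H mu)``.  The Bayesian mean
squared error (BMSE) of the minimum-mean-squared-error (MMSE) prediction of a
linear functional ``h' theta`` equals ``h' Sigma h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, stats

__all__ = [
    "GaussianPrior",
    "NoiseSpec",
    "DesignMatrix",
    "PosteriorSummary",
    "mmse_estimate",
    "posterior_covariance",
    "prediction_bmse",
]

# relative tolerance used when symmetrising matrices that should be symmetric
_SYM_RTOL = 1e-10


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a + a.T)


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian population prior ``theta ~ N(mean, covariance)``.

    ``covariance`` is the between-subjects covariance matrix; it must be
    symmetric positive definite (perfectly correlated priors, |rho| = 1, are
    rejected because the precision matrix would not exist).
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if cov.shape != (mean.size, mean.size):
            raise ValueError(
                f"covariance shape {cov.shape} does not match mean length {mean.size}"
            )
        if not np.allclose(cov, cov.T, rtol=_SYM_RTOL, atol=0.0):
            raise ValueError("prior covariance must be symmetric")
        cov = _symmetrize(cov)
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0.0:
            raise ValueError(
                "prior covariance must be positive definite "
                f"(smallest eigenvalue {eigvals.min():.3e})"
            )
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def dim(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class NoiseSpec:
    """Per-response-type within-subjects error standard deviations.

    ``sigma_by_type`` maps a response-type label (1-based by convention, but
    any hashable label works) to the error s.d. of that type.  Errors are
    independent across observations, so the implied error covariance matrix is
    diagonal.
    """

    sigma_by_type: Mapping[int, float]

    def __post_init__(self) -> None:
        clean = {}
        for key, sd in dict(self.sigma_by_type).items():
            sd = float(sd)
            if not sd > 0.0:
                raise ValueError(f"error s.d. for type {key!r} must be > 0, got {sd}")
            clean[key] = sd
        object.__setattr__(self, "sigma_by_type", clean)

    def sigma(self, response_type: int) -> float:
        return self.sigma_by_type[response_type]

    def variances(self, type_of_row: Sequence[int]) -> np.ndarray:
        """Diagonal of the error covariance for the given row types."""
        return np.array([self.sigma_by_type[t] ** 2 for t in type_of_row])


@dataclass(frozen=True)
class DesignMatrix:
    """Design matrix H together with the response type of each row."""

    rows: np.ndarray
    type_of_row: np.ndarray

    def __post_init__(self) -> None:
        rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if rows.size == 0:
            rows = rows.reshape(0, rows.shape[-1] if rows.ndim == 2 else 0)
        types = np.asarray(self.type_of_row)
        if rows.shape[0] != types.size:
            raise ValueError(
                f"{rows.shape[0]} design rows but {types.size} row types"
            )
        if rows.size and not np.all(np.isfinite(rows)):
            raise ValueError("design matrix entries must be finite")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "type_of_row", types)

    @property
    def n_obs(self) -> int:
        return self.rows.shape[0]

    @property
    def n_params(self) -> int:
        return self.rows.shape[1]

    @staticmethod
    def empty(n_params: int) -> "DesignMatrix":
        return DesignMatrix(np.empty((0, n_params)), np.empty(0, dtype=int))


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior-mean estimate with covariance, prediction BMSE and CI.

    ``bmse_prediction`` and ``ci`` refer to the linear functional ``h' theta``
    requested when the summary was produced (default: the first parameter,
    i.e. the primary response mean).
    """

    estimate: np.ndarray
    covariance: np.ndarray
    bmse_prediction: float
    ci: tuple[float, float]
    level: float = 0.95
    h: np.ndarray = field(default=None, repr=False)

    @property
    def prediction(self) -> float:
        """Point prediction of the requested functional h' theta."""
        return float(self.h @ self.estimate)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate.tolist(),
            "covariance": self.covariance.tolist(),
            "prediction": self.prediction,
            "bmse_prediction": self.bmse_prediction,
            "ci": list(self.ci),
            "level": self.level,
        }


def _check_dims(prior: GaussianPrior, design: DesignMatrix) -> None:
    if design.n_params != prior.dim:
        raise ValueError(
            f"design has {design.n_params} columns but prior dimension is {prior.dim}"
        )


def posterior_covariance(
    prior: GaussianPrior, design: DesignMatrix, noise: NoiseSpec
) -> np.ndarray:
    """Posterior covariance ``(C_theta^{-1} + H' C_eps^{-1} H)^{-1}``.

    Independent of the observed values; with an empty design it is the prior
    covariance itself.  Computed with Cholesky solves, no explicit inverses.
    """
    _check_dims(prior, design)
    if design.n_obs == 0:
        return prior.covariance.copy()
    prior_chol = linalg.cho_factor(prior.covariance, lower=True)
    prior_precision = linalg.cho_solve(prior_chol, np.eye(prior.dim))
    w = 1.0 / noise.variances(design.type_of_row)  # diagonal C_eps^{-1}
    precision = prior_precision + (design.rows * w[:, None]).T @ design.rows
    precision = _symmetrize(precision)
    try:
        prec_chol = linalg.cho_factor(precision, lower=True)
    except linalg.LinAlgError as err:  # pragma: no cover - PD prior makes this rare
        raise ValueError("posterior precision is singular") from err
    cov = linalg.cho_solve(prec_chol, np.eye(prior.dim))
    return _symmetrize(cov)


def mmse_estimate(
    prior: GaussianPrior,
    design: DesignMatrix,
    noise: NoiseSpec,
    y: np.ndarray,
    h: np.ndarray | None = None,
    level: float = 0.95,
) -> PosteriorSummary:
    """MMSE (posterior-mean) estimate of theta from observations ``y``.

    Parameters
    ----------
    h
        Prediction functional; the summary reports the BMSE and a Gaussian
        posterior credible interval for ``h' theta``.  Defaults to the unit
        vector on the first parameter.
    level
        Credible-interval level (the posterior is exactly Gaussian here).
    """
    _check_dims(prior, design)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.size != design.n_obs:
        raise ValueError(f"{y.size} observations but design has {design.n_obs} rows")
    if h is None:
        h = np.eye(prior.dim)[0]
    h = np.asarray(h, dtype=float)

    cov = posterior_covariance(prior, design, noise)
    if design.n_obs == 0:
        estimate = prior.mean.copy()
    else:
        w = 1.0 / noise.variances(design.type_of_row)
        rhs = design.rows.T @ (w * (y - design.rows @ prior.mean))
        estimate = prior.mean + cov @ rhs

    bmse = prediction_bmse(h, cov)
    center = float(h @ estimate)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(bmse)
    return PosteriorSummary(
        estimate=estimate,
        covariance=cov,
        bmse_prediction=bmse,
        ci=(center - half, center + half),
        level=level,
        h=h,
    )


def prediction_bmse(h: np.ndarray, posterior_cov: np.ndarray) -> float:
    """BMSE of the MMSE prediction of ``h' theta``: the quadratic form h' Sigma h."""
    h = np.asarray(h, dtype=float)
    posterior_cov = np.asarray(posterior_cov, dtype=float)
    if h.size != posterior_cov.shape[0]:
        raise ValueError(
            f"functional length {h.size} does not match covariance dimension "
            f"{posterior_cov.shape[0]}"
        )
    return float(h @ posterior_cov @ h)
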