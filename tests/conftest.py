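import numpy as np
import pytest

from bayescast import (
    AccuracyTarget,
    BivariateInterceptPrior,
    CostSpec,
    NoiseSpec,
)

# Sleep-study worked example: PSG (primary) and actigraphy (secondary)
# measurements of wakefulness after sleep onset, in minutes.
WASO = dict(delta1=21.0, delta2=21.0, rho=0.69, sigma1=32.0, sigma2=21.0,
            c1=1250.0, c2=150.0, eta=15.0)


@pytest.fixture
def waso_prior() -> BivariateInterceptPrior:
    return BivariateInterceptPrior(54.0, 32.0, WASO["delta1"], WASO["delta2"], WASO["rho"])


@pytest.fixture
def waso_noise() -> NoiseSpec:
    return NoiseSpec({1: WASO["sigma1"], 2: WASO["sigma2"]})


@pytest.fixture
def waso_costs() -> CostSpec:
    return CostSpec(WASO["c1"], WASO["c2"])


@pytest.fixture
def waso_target() -> AccuracyTarget:
    return AccuracyTarget(WASO["eta"])


def grid_posterior_moments(mu, cov, H, sigmas, y, half_width=6.0, n=241):
    """Brute-force posterior mean/covariance by dense grid integration.

    Independent of the linear-algebra path under test: evaluates the
    unnormalised Gaussian posterior density on a regular grid over
    mu +/- half_width prior s.d.s per dimension and averages.
    Only practical for dimension <= 4.
    """
    mu = np.asarray(mu, float)
    cov = np.asarray(cov, float)
    d = mu.size
    sds = np.sqrt(np.diag(cov))
    axes = [np.linspace(m - half_width * s, m + half_width * s, n) for m, s in zip(mu, sds)]
    mesh = np.meshgrid(*axes, indexing="ij")
    theta = np.stack([m.ravel() for m in mesh], axis=1)
    prec = np.linalg.inv(cov)
    resid = theta - mu
    logp = -0.5 * np.einsum("ni,ij,nj->n", resid, prec, resid)
    if len(y):
        H = np.asarray(H, float)
        pred = theta @ H.T
        logp = logp - 0.5 * np.sum(((np.asarray(y) - pred) / np.asarray(sigmas)) ** 2, axis=1)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    mean = w @ theta
    centred = theta - mean
    covp = (w[:, None] * centred).T @ centred
    return mean, covp
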