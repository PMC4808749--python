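"""Minimal-cost allocation of primary/secondary measurements.

Given per-observation costs (c1, c2) and a target root-BMSE eta for the
primary intercept of the bivariate random-intercept model, find the
measurement counts (m1, m2) that reach average accuracy eta^2 at minimal
total cost ``c1*m1 + c2*m2``.

The accuracy constraint pins m1 to m2 through

    m1(m2) = sigma1^2 (1/eta^2 - 1/delta1^2 - lambda(m2)),

so the problem reduces to a one-dimensional minimisation over m2.  The cost
curve has at most one interior stationary point,

    m2+ = sigma2 (sqrt(c1/c2) delta2 sigma1 |rho| - delta1 sigma2)
          / (delta1 delta2^2 (1 - rho^2)),

and the solution falls into exactly one of three regimes:

``primary_only``
    secondary data too expensive per unit information
    (c2/c1 > (delta2^2/sigma2^2)/(delta1^2/sigma1^2) * rho^2, equivalently
    m2+ <= 0); collect m1 = sigma1^2(1/eta^2 - 1/delta1^2) primary
    observations only.
``interior``
    m2+ lies inside the feasible interval; collect m2 = m2+ and m1 = m1(m2+).
``secondary_only``
    m2+ exceeds the upper feasibility bound (which exists only when the
    target is reachable with secondary data alone, delta1^2(1-rho^2) <=
    eta^2); collect only secondary observations at that bound.

Integer designs are found by rounding-neighbourhood search (with axis
candidates) or exhaustive enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intercept_models import (
    BivariateInterceptPrior,
    DesignCounts,
    bivariate_bmse_primary,
    lambda_secondary,
)
from .linear_gaussian_core import NoiseSpec

__all__ = [
    "CostSpec",
    "AccuracyTarget",
    "DesignSolution",
    "InfeasibleTarget",
    "required_primary_count",
    "feasible_m2_bounds",
    "critical_point_m2",
    "solve_continuous_design",
    "solve_integer_design",
    "cost_curve",
]

# feasibility slack for "BMSE <= eta^2" checks on integer candidates, relative
_FEAS_RTOL = 1e-9


class InfeasibleTarget(ValueError):
    """Raised when the requested accuracy cannot beat the prior alone."""


@dataclass(frozen=True)
class CostSpec:
    """Per-observation costs (opaque currency units)."""

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("costs must be > 0")

    def total(self, m1: float, m2: float) -> float:
        return self.c1 * m1 + self.c2 * m2


@dataclass(frozen=True)
class AccuracyTarget:
    """Target root-BMSE eta, in response units (squared internally)."""

    eta: float

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be > 0")

    @property
    def eta_sq(self) -> float:
        return self.eta**2


@dataclass(frozen=True)
class DesignSolution:
    """A measurement allocation and its cost/accuracy bookkeeping."""

    m1: float
    m2: float
    case: str  # interior | primary_only | secondary_only
    total_cost: float
    achieved_bmse: float
    m1_int: int | None = None
    m2_int: int | None = None

    def to_dict(self) -> dict:
        d = {
            "m1": self.m1,
            "m2": self.m2,
            "case": self.case,
            "total_cost": self.total_cost,
            "achieved_bmse": self.achieved_bmse,
        }
        if self.m1_int is not None:
            d["m1_int"] = self.m1_int
            d["m2_int"] = self.m2_int
        return d


def _check_target(target: AccuracyTarget, prior: BivariateInterceptPrior) -> None:
    if target.eta_sq >= prior.delta1**2:
        raise InfeasibleTarget(
            f"target eta={target.eta} is no better than the prior s.d. "
            f"delta1={prior.delta1}; no data are needed"
        )


def required_primary_count(
    target: AccuracyTarget,
    m2: float,
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
) -> float:
    """Primary count reaching BMSE = eta^2 given m2 secondary observations.

    ``m1 = sigma1^2 (1/eta^2 - 1/delta1^2 - lambda(m2))``.  May be negative
    when m2 alone over-achieves the target; the caller clamps or interprets.
    """
    _check_target(target, prior)
    lam = lambda_secondary(prior, noise.sigma(2), m2)
    return noise.sigma(1) ** 2 * (
        1.0 / target.eta_sq - 1.0 / prior.delta1**2 - lam
    )


def feasible_m2_bounds(
    target: AccuracyTarget, prior: BivariateInterceptPrior, noise: NoiseSpec
) -> tuple[float, float]:
    """Feasible interval [0, upper] for m2 under the m1 >= 0 constraint.

    The upper bound is finite only when the target is reachable with the
    secondary response alone, i.e. ``delta1^2 (1-rho^2) <= eta^2``; otherwise
    the interval is [0, inf).
    """
    _check_target(target, prior)
    d1sq, d2sq = prior.delta1**2, prior.delta2**2
    floor = d1sq * (1.0 - prior.rho**2)  # secondary-only BMSE floor
    if floor > target.eta_sq:
        return 0.0, math.inf
    num = noise.sigma(2) ** 2 * (1.0 / target.eta_sq - 1.0 / d1sq)
    den = d2sq * (1.0 - prior.rho**2) * (1.0 / floor - 1.0 / target.eta_sq)
    return 0.0, num / den


def critical_point_m2(
    prior: BivariateInterceptPrior, noise: NoiseSpec, costs: CostSpec
) -> float:
    """Stationary point m2+ of the cost curve (the negative root is discarded).

    ``m2+ = sigma2 (sqrt(c1/c2) delta2 sigma1 |rho| - delta1 sigma2)
    / (delta1 delta2^2 (1-rho^2))``.  Uses |rho|: negative correlation is as
    informative as positive (the BMSE depends on rho only through rho^2).
    May be <= 0, signalling that no interior minimum exists.
    """
    if prior.rho == 0.0:
        raise ValueError("no interior critical point when rho = 0")
    s1, s2 = noise.sigma(1), noise.sigma(2)
    num = s2 * (
        math.sqrt(costs.c1 / costs.c2) * prior.delta2 * s1 * abs(prior.rho)
        - prior.delta1 * s2
    )
    den = prior.delta1 * prior.delta2**2 * (1.0 - prior.rho**2)
    return num / den


def solve_continuous_design(
    target: AccuracyTarget,
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
    costs: CostSpec,
) -> DesignSolution:
    """Continuous minimal-cost design achieving BMSE exactly eta^2."""
    _check_target(target, prior)
    s1, s2 = noise.sigma(1), noise.sigma(2)
    _, m2_upper = feasible_m2_bounds(target, prior, noise)

    # secondary data too costly per unit information -> no secondary data
    primary_only = (
        prior.rho == 0.0
        or costs.c2 / costs.c1
        > (prior.delta2**2 / s2**2) / (prior.delta1**2 / s1**2) * prior.rho**2
    )
    if primary_only:
        m1 = required_primary_count(target, 0.0, prior, noise)
        m1, m2, case = m1, 0.0, "primary_only"
    else:
        m2_plus = critical_point_m2(prior, noise, costs)
        if m2_plus > m2_upper:
            m1, m2, case = 0.0, m2_upper, "secondary_only"
        else:
            m1 = required_primary_count(target, m2_plus, prior, noise)
            m2, case = m2_plus, "interior"
    bmse = bivariate_bmse_primary(prior, noise, DesignCounts(max(m1, 0.0), m2))
    return DesignSolution(
        m1=m1, m2=m2, case=case, total_cost=costs.total(m1, m2), achieved_bmse=bmse
    )


def _feasible(
    m1: int,
    m2: int,
    target: AccuracyTarget,
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
) -> bool:
    bmse = bivariate_bmse_primary(prior, noise, DesignCounts(m1, m2))
    return bmse <= target.eta_sq * (1.0 + _FEAS_RTOL)


def solve_integer_design(
    target: AccuracyTarget,
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
    costs: CostSpec,
    search_radius: int = 5,
    exhaustive: bool = False,
    max_count: int = 50,
) -> DesignSolution:
    """Integer minimal-cost design with BMSE <= eta^2.

    By default searches a +/- ``search_radius`` neighbourhood of the rounded
    continuous solution plus the primary-only and secondary-only axis
    candidates (plain rounding can miss the optimum).  ``exhaustive=True``
    enumerates the full grid ``0..max_count`` in each count instead.
    """
    cont = solve_continuous_design(target, prior, noise, costs)

    candidates: set[tuple[int, int]] = set()
    if exhaustive:
        candidates.update(
            (i, j) for i in range(max_count + 1) for j in range(max_count + 1)
        )
    else:
        c1 = max(0, math.floor(cont.m1)) if cont.m1 > 0 else 0
        c2 = max(0, math.floor(cont.m2)) if cont.m2 > 0 else 0
        for i in range(max(0, c1 - search_radius), c1 + search_radius + 2):
            for j in range(max(0, c2 - search_radius), c2 + search_radius + 2):
                candidates.add((i, j))
        # axis candidates: pure-primary and (if feasible) pure-secondary designs
        m1_axis = required_primary_count(target, 0.0, prior, noise)
        candidates.add((math.ceil(m1_axis), 0))
        _, m2_upper = feasible_m2_bounds(target, prior, noise)
        if math.isfinite(m2_upper):
            candidates.add((0, math.ceil(m2_upper)))

    best: tuple[float, int, int] | None = None
    for m1, m2 in sorted(candidates):
        if not _feasible(m1, m2, target, prior, noise):
            continue
        cost = costs.total(m1, m2)
        key = (cost, m1 + m2, m1)
        if best is None or key < (best[0], best[1] + best[2], best[1]):
            best = (cost, m1, m2)
    if best is None:
        raise InfeasibleTarget(
            "no feasible integer design found in the search window; "
            "widen search_radius or use exhaustive=True"
        )
    cost, m1_int, m2_int = best
    bmse = bivariate_bmse_primary(prior, noise, DesignCounts(m1_int, m2_int))
    return DesignSolution(
        m1=cont.m1,
        m2=cont.m2,
        case=cont.case,
        total_cost=cost,
        achieved_bmse=bmse,
        m1_int=m1_int,
        m2_int=m2_int,
    )


def cost_curve(
    target: AccuracyTarget,
    prior: BivariateInterceptPrior,
    noise: NoiseSpec,
    costs: CostSpec,
    m2_grid: np.ndarray,
) -> pd.DataFrame:
    """Total cost against secondary sample size along the accuracy constraint.

    For each m2 in the grid, ``m1_required`` is the (possibly negative)
    continuous primary count reaching eta^2; ``feasible`` marks m1 >= 0, and
    the total cost clamps m1 at zero outside the feasible range.
    """
    m2_grid = np.asarray(m2_grid, dtype=float)
    m1_req = np.array(
        [required_primary_count(target, m2, prior, noise) for m2 in m2_grid]
    )
    total = costs.c1 * np.clip(m1_req, 0.0, None) + costs.c2 * m2_grid
    return pd.DataFrame(
        {
            "m2": m2_grid,
            "m1_required": m1_req,
            "total_cost": total,
            "feasible": m1_req >= 0.0,
        }
    )
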