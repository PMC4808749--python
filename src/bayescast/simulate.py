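"""Seeded synthetic populations and observation tables.

Generators for every simulation scenario used elsewhere in the package:
subject-specific parameters drawn from a population prior, and long-format
observation tables (subject_id, response_type, time, value) produced by one
of the three model families (random intercept, linearised homeostat,
circadian sinusoid) plus iid Gaussian measurement noise.  Every generator is
a pure function of its parameters and seed, and tables carry enough metadata
to be regenerated bit-identically.

Named scenario presets (fig2, fig3, fig4_5, fig6, fig7, sec9) ship as YAML
files describing the illustration settings used throughout the docs/tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .circadian_forecast import PERIOD, CircadianPrior
from .homeostat_timing import BivariateTimingPrior, UnivariateTimingPrior
from .intercept_models import BivariateInterceptPrior, UnivariateInterceptPrior
from .linear_gaussian_core import GaussianPrior, NoiseSpec

__all__ = [
    "ObservationTable",
    "SubjectParameterTable",
    "draw_subjects",
    "simulate_observations",
    "load_scenario",
    "list_scenarios",
]

OBS_COLUMNS = ["subject_id", "response_type", "time", "value"]


@dataclass(frozen=True)
class SubjectParameterTable:
    """Per-subject true parameter vectors and the seed that produced them."""

    data: pd.DataFrame
    seed: int | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ObservationTable:
    """Long-format observations plus regeneration metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if len(self.data):
            if not self.data["response_type"].isin([1, 2]).all():
                raise ValueError("response_type must be 1 or 2")
            if not np.isfinite(self.data["value"].astype(float)).all():
                raise ValueError("values must be finite")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @staticmethod
    def read_csv(path) -> "ObservationTable":
        df = pd.read_csv(path)
        return ObservationTable(df[OBS_COLUMNS])

    def values_for(self, subject_id, response_type: int) -> np.ndarray:
        mask = (self.data["subject_id"] == subject_id) & (
            self.data["response_type"] == response_type
        )
        return self.data.loc[mask, "value"].to_numpy()


def _param_columns(prior) -> list[str]:
    if isinstance(prior, UnivariateInterceptPrior):
        return ["theta"]
    if isinstance(prior, BivariateInterceptPrior):
        return ["theta1", "theta2"]
    if isinstance(prior, UnivariateTimingPrior):
        return ["alpha", "beta"]
    if isinstance(prior, BivariateTimingPrior):
        return ["alpha1", "alpha2", "beta1", "beta2"]
    if isinstance(prior, CircadianPrior):
        return ["A1", "A2", "phi"]
    if isinstance(prior, GaussianPrior):
        return [f"theta{i + 1}" for i in range(prior.dim)]
    raise TypeError(f"unsupported prior type {type(prior).__name__}")


def draw_subjects(prior, n: int, seed: int) -> SubjectParameterTable:
    """Draw n iid subject parameter vectors from a population prior.

    Accepts any of the package's prior types; circadian priors draw the
    amplitude pair and the phase from their respective Gaussians.
    Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = _param_columns(prior)
    if isinstance(prior, CircadianPrior):
        amps = rng.multivariate_normal(prior.amp_mean, prior.amp_cov, size=n)
        phi = rng.normal(prior.phase_mean, np.sqrt(prior.phase_var), size=n)
        values = np.column_stack([amps, phi])
    else:
        gp = prior if isinstance(prior, GaussianPrior) else prior.to_gaussian_prior()
        values = rng.multivariate_normal(gp.mean, gp.covariance, size=n)
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "subject_id", np.arange(1, n + 1))
    return SubjectParameterTable(df, seed=seed)


def _model_mean(model: str, row: pd.Series, response_type: int, t: float) -> float:
    if model == "intercept":
        if "theta" in row.index:
            return float(row["theta"])
        return float(row[f"theta{response_type}"])
    if model == "homeostat":
        if "alpha" in row.index:
            return float(row["alpha"] + row["beta"] * t)
        return float(row[f"alpha{response_type}"] + row[f"beta{response_type}"] * t)
    if model == "circadian":
        return float(
            row[f"A{response_type}"]
            * np.sin(2.0 * np.pi * (t - row["phi"]) / PERIOD)
        )
    raise ValueError(f"unknown model tag {model!r}")


def simulate_observations(
    params: SubjectParameterTable,
    model: str,
    schedule: Mapping[int, Sequence[float]],
    noise: NoiseSpec,
    seed: int,
) -> ObservationTable:
    """Observation table for every subject at the scheduled times.

    ``schedule`` maps response type (1/2) to its measurement times; values
    are the model mean at (subject parameters, time) plus iid Gaussian noise
    with the type-specific s.d.  With a zero-variance limit in mind, the
    noise draw is still consumed per observation so tables with different
    sigmas share no randomness structure.
    """
    if not any(len(v) for v in schedule.values()):
        raise ValueError("schedule must contain at least one measurement time")
    rng = np.random.default_rng(seed)
    records = []
    for _, row in params.data.iterrows():
        for r in sorted(schedule):
            sd = noise.sigma(r)
            for t in schedule[r]:
                mean = _model_mean(model, row, r, float(t))
                records.append(
                    (row["subject_id"], r, float(t), mean + rng.normal(0.0, sd))
                )
    df = pd.DataFrame(records, columns=OBS_COLUMNS)
    df["subject_id"] = df["subject_id"].astype(params.data["subject_id"].dtype)
    meta = {
        "model": model,
        "schedule": {int(k): [float(t) for t in v] for k, v in schedule.items()},
        "sigma_by_type": dict(noise.sigma_by_type),
        "seed": seed,
    }
    return ObservationTable(df, metadata=meta)


def list_scenarios() -> list[str]:
    root = importlib.resources.files("bayescast") / "scenarios"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str) -> dict:
    """Load a named illustration preset (fig2, fig3, fig4_5, fig6, fig7, sec9)."""
    path = importlib.resources.files("bayescast") / "scenarios" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError as err:
        raise KeyError(
            f"unknown scenario {name!r}; available: {list_scenarios()}"
        ) from err
    return yaml.safe_load(text)
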