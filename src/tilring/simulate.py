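"""Synthetic ring-study generator.

Emulates the two-way random-effects structure of a multi-reader sTIL
concordance exercise:

    Y_ij = mu_i + b_j + mean of m region deviations + e_ij

where mu_i is the slide's true stromal-TIL percentage, b_j a reader's
systematic bias, region deviations N(0, sigma_region^2) capture within-slide
lymphocyte heterogeneity sampled independently by each reader (averaging m
regions shrinks this component by 1/m, the mechanism behind the
multiple-region scoring protocol), and e_ij residual scoring noise.  Scores
are optionally snapped to a rounding grid, clipped to [0, 100], and sporadic
cells blanked to mimic missing reads.

The population intraclass correlation implied by a configuration is

    ICC = Var(mu) / (Var(mu) + sigma_reader^2 + sigma_region^2 / m + sigma_error^2)

computed from the configured variances, before rounding or clipping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Annotated, Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .core_io import ScoreMatrix

__all__ = [
    "BetaCases",
    "NormalCases",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_study",
    "population_icc",
    "inject_missing",
    "DegenerateConfigError",
]


class DegenerateConfigError(ValueError):
    """All variance components are zero; the ICC is undefined."""


class BetaCases(BaseModel):
    """Right-skewed true-score distribution: scale * Beta(alpha, beta).

    The default Beta(0.8, 2.6) scaled to 0-100 puts most slides below 30%
    sTILs with a long right tail, the shape typical of breast-cancer cohorts.
    """

    kind: Literal["beta"] = "beta"
    alpha: float = Field(default=0.8, gt=0)
    beta: float = Field(default=2.6, gt=0)
    scale: float = Field(default=100.0, gt=0)

    def mean(self) -> float:
        return self.scale * self.alpha / (self.alpha + self.beta)

    def variance(self) -> float:
        a, b = self.alpha, self.beta
        return self.scale**2 * a * b / ((a + b) ** 2 * (a + b + 1))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.scale * rng.beta(self.alpha, self.beta, size=n)


class NormalCases(BaseModel):
    """Gaussian true-score distribution, for model-validation studies."""

    kind: Literal["normal"] = "normal"
    mean_: float = Field(default=30.0, alias="mean")
    sd: float = Field(default=15.0, ge=0)

    model_config = {"populate_by_name": True}

    def mean(self) -> float:
        return self.mean_

    def variance(self) -> float:
        return self.sd**2

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean_, self.sd, size=n)


CaseDistribution = Annotated[Union[BetaCases, NormalCases], Field(discriminator="kind")]


class SimulationConfig(BaseModel):
    """Generative parameters for one simulated ring study.

    Defaults mirror the first ring study's design (60 core-biopsy slides
    read by 32 pathologists, single region per slide, no reference-image
    anchoring) with noise levels that put the population ICC near 0.7.
    All SDs are in percent-sTIL units.
    """

    n_slides: int = Field(default=60, ge=2)
    n_readers: int = Field(default=32, ge=2)
    case_distribution: CaseDistribution = Field(default_factory=BetaCases)
    sigma_reader: float = Field(default=5.0, ge=0)
    sigma_region: float = Field(default=11.0, ge=0)
    n_regions: int = Field(default=1, ge=1)
    sigma_error: float = Field(default=7.0, ge=0)
    rounding_increment: float = Field(default=0.0, ge=0)
    missing_rate: float = Field(default=0.0, ge=0, lt=1)
    clip: bool = True
    seed: int = 0
    study_label: str = "simulated ring study"

    @model_validator(mode="after")
    def _check_variance(self):
        if (
            self.case_distribution.variance() == 0
            and self.sigma_reader == 0
            and self.sigma_region == 0
            and self.sigma_error == 0
        ):
            raise DegenerateConfigError("all variance components are zero")
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.model_validate(yaml.safe_load(text))


@dataclass(frozen=True)
class SimulationTruth:
    """Latent values behind a simulated study, plus its population ICC."""

    mu: np.ndarray  # per-slide true scores
    b: np.ndarray  # per-reader biases
    config: SimulationConfig
    population_icc: float


def population_icc(config: SimulationConfig) -> float:
    """Fraction of score variance attributable to true between-slide differences.

    Var(mu) / (Var(mu) + sigma_reader^2 + sigma_region^2/m + sigma_error^2),
    from the configured (not sampled) variances, before rounding/clipping.
    """
    var_mu = config.case_distribution.variance()
    denom = (
        var_mu
        + config.sigma_reader**2
        + config.sigma_region**2 / config.n_regions
        + config.sigma_error**2
    )
    if denom == 0:
        raise DegenerateConfigError("all variance components are zero")
    return var_mu / denom


def simulate_study(config: SimulationConfig) -> tuple[ScoreMatrix, SimulationTruth]:
    """Draw one ring study under the configured two-way random-effects model.

    The seed drives independent substreams for cases, reader biases, region
    sampling, residual noise, and the missing mask, so e.g. changing the
    missing rate does not perturb the scores themselves.
    """
    ss = np.random.SeedSequence(config.seed)
    s_mu, s_b, s_reg, s_err, s_miss = [np.random.default_rng(c) for c in ss.spawn(5)]
    n, k, m = config.n_slides, config.n_readers, config.n_regions

    mu = config.case_distribution.sample(s_mu, n)
    b = s_b.normal(0.0, config.sigma_reader, size=k)
    region = s_reg.normal(0.0, config.sigma_region, size=(n, k, m)).mean(axis=2)
    err = s_err.normal(0.0, config.sigma_error, size=(n, k))
    y = mu[:, None] + b[None, :] + region + err
    if config.rounding_increment > 0:
        y = np.round(y / config.rounding_increment) * config.rounding_increment
    if config.clip:
        y = np.clip(y, 0.0, 100.0)

    slide_ids = tuple(f"s{i + 1:03d}" for i in range(n))
    reader_ids = tuple(f"r{j + 1:02d}" for j in range(k))
    matrix = ScoreMatrix(slide_ids, reader_ids, y, study_label=config.study_label)
    if config.missing_rate > 0:
        matrix = _apply_missing(matrix, config.missing_rate, s_miss)
    truth = SimulationTruth(mu=mu, b=b, config=config,
                            population_icc=population_icc(config))
    return matrix, truth


def _apply_missing(matrix: ScoreMatrix, rate: float,
                   rng: np.random.Generator, max_attempts: int = 100) -> ScoreMatrix:
    for _ in range(max_attempts):
        mask = rng.random(matrix.scores.shape) < rate
        if not (mask | matrix.mask).all(axis=1).any():
            scores = matrix.scores.copy()
            scores[mask] = np.nan
            return ScoreMatrix(matrix.slide_ids, matrix.reader_ids, scores,
                               matrix.study_label)
    raise ValueError(
        f"missing rate {rate} left a slide with no scores after {max_attempts} attempts"
    )


def inject_missing(matrix: ScoreMatrix, rate: float, seed: int) -> ScoreMatrix:
    """Blank each cell independently with probability ``rate``.

    The whole mask is redrawn (up to 100 attempts) if it would leave any
    slide with no observed score, since per-slide mean imputation needs at
    least one read per slide.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    if rate == 0:
        return matrix
    return _apply_missing(matrix, rate, np.random.default_rng(seed))
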