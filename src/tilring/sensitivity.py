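"""Outcome sensitivity to sTIL scoring deviations, and cutpoint misassignment.

sTILs are prognostic in early triple-negative breast cancer: higher stromal
TIL percentages predict better invasive disease-free survival (iDFS).  A
scoring deviation therefore shifts the estimated outcome, and when a
cutpoint triggers a treatment decision, scoring noise near the cutpoint can
misassign patients.  This module propagates deviations through a pluggable
prognostic model, computes Gaussian misassignment probabilities at a single
cutpoint, and evaluates the indeterminate-zone strategy in which scores
between a low and a high threshold trigger no confident call.

The built-in model is an illustrative exponential proportional-hazards
stand-in, calibrated so its whole-percent 5-year iDFS values at sTILs
30/20/40 are 76/73/79 — the behaviour of published pooled-trial prognosis
tools — and is labelled as such; it is not a fitted clinical model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

__all__ = [
    "PrognosticModel",
    "SensitivityResult",
    "DeviationRow",
    "illustrative_model",
    "deviation_grid",
    "misassignment_probability",
    "three_zone_classify",
    "zone_misassignment_probability",
]


@dataclass(frozen=True)
class PrognosticModel:
    """Evaluable contract (horizon_years, stil_percent) -> event-free survival.

    ``survival`` must return probabilities in [0, 1], non-increasing in the
    horizon and (for models encoding the protective direction of sTILs)
    non-decreasing in the sTIL percentage.
    """

    survival: Callable[[float, float], float]
    name: str
    params: dict

    def __call__(self, horizon_years: float, stil: float) -> float:
        return self.survival(horizon_years, stil)


def illustrative_model(
    baseline_cumhaz: float = 0.274, hr_per_10: float = 0.87
) -> PrognosticModel:
    """Exponential proportional-hazards stand-in for a pooled-trial iDFS tool.

    S(t, s) = exp(-baseline_cumhaz * (t/5) * hr_per_10^((s - 30) / 10))

    ``baseline_cumhaz`` is the 5-year cumulative hazard at the reference
    sTIL level of 30%; ``hr_per_10`` < 1 is the hazard ratio per +10 sTIL
    points (protective).  The defaults are a reverse-engineered calibration
    to a published worked example at whole-percent rounding, not fitted
    coefficients.
    """
    if baseline_cumhaz <= 0 or hr_per_10 <= 0:
        raise ValueError("baseline_cumhaz and hr_per_10 must be positive")

    def survival(horizon_years: float, stil: float) -> float:
        if horizon_years < 0:
            raise ValueError("horizon must be non-negative")
        if not 0 <= stil <= 100:
            raise ValueError(f"sTIL score {stil} outside [0, 100]")
        h = baseline_cumhaz * (horizon_years / 5.0) * hr_per_10 ** ((stil - 30.0) / 10.0)
        return float(np.exp(-h))

    return PrognosticModel(
        survival=survival,
        name="illustrative exponential PH (synthetic calibration)",
        params={"baseline_cumhaz": baseline_cumhaz, "hr_per_10": hr_per_10},
    )


@dataclass(frozen=True)
class DeviationRow:
    delta: float
    stil: float
    outcome: float
    outcome_delta: float  # vs the true-score outcome


@dataclass(frozen=True)
class SensitivityResult:
    true_stil: float
    horizon: float
    true_outcome: float
    rows: tuple[DeviationRow, ...]
    model_name: str

    def to_dict(self) -> dict:
        return {
            "true_stil": self.true_stil,
            "horizon_years": self.horizon,
            "true_outcome": self.true_outcome,
            "model": self.model_name,
            "deviations": [
                {
                    "delta": r.delta,
                    "stil": r.stil,
                    "outcome": r.outcome,
                    "outcome_delta": r.outcome_delta,
                    "outcome_pct": round(100 * r.outcome),
                }
                for r in self.rows
            ],
        }


DEFAULT_DELTAS: tuple[float, ...] = (-20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0)


def deviation_grid(
    model: PrognosticModel,
    true_stil: float,
    deltas=DEFAULT_DELTAS,
    horizon: float = 5.0,
) -> SensitivityResult:
    """Evaluate the model at the true score and at each scoring deviation.

    Deviations that would leave [0, 100] raise rather than clamp silently.
    """
    if not 0 <= true_stil <= 100:
        raise ValueError(f"true sTIL {true_stil} outside [0, 100]")
    for d in deltas:
        if not 0 <= true_stil + d <= 100:
            raise ValueError(f"deviation {d:+g} takes sTIL {true_stil} outside [0, 100]")
    truth = model(horizon, true_stil)
    rows = tuple(
        DeviationRow(
            delta=float(d),
            stil=float(true_stil + d),
            outcome=(out := model(horizon, true_stil + d)),
            outcome_delta=out - truth,
        )
        for d in deltas
    )
    return SensitivityResult(float(true_stil), float(horizon), truth, rows, model.name)


def misassignment_probability(true_stil: float, sigma: float, cutpoint: float) -> float:
    """Probability an observed score lands on the wrong side of a cutpoint.

    The observed score is true + N(0, sigma^2) (unbiased scoring noise;
    sigma can be taken from a slide's inter-reader SD).  The boundary
    convention matches dichotomize: score >= cutpoint is the upper class.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    true_upper = true_stil >= cutpoint
    if sigma == 0:
        return 0.0  # observed == true, always the correct side
    z = (cutpoint - true_stil) / sigma
    # P(observed < cutpoint) = Phi(z); P(observed >= cutpoint) = 1 - Phi(z)
    return float(norm.cdf(z)) if true_upper else float(norm.sf(z))


def three_zone_classify(score: float, low: float, high: float) -> str:
    """Classify against an indeterminate band: below / indeterminate / above.

    below iff score < low; above iff score >= high (consistent with the
    single-cutpoint boundary convention); otherwise indeterminate.
    """
    if low >= high:
        raise ValueError(f"band requires low < high, got {low} >= {high}")
    if score < low:
        return "below"
    if score >= high:
        return "above"
    return "indeterminate"


def zone_misassignment_probability(
    true_stil: float, sigma: float, low: float, high: float
) -> float:
    """Probability of a confident call on the wrong side of the band.

    Only confident-wrong calls count: a truly-below score observed >= high,
    or a truly-above score observed < low.  Indeterminate observations, and
    truths inside the band, incur no misassignment.  Widening the band can
    therefore only reduce this probability.
    """
    if low >= high:
        raise ValueError(f"band requires low < high, got {low} >= {high}")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return 0.0
    if true_stil < low:
        return float(norm.sf((high - true_stil) / sigma))
    if true_stil >= high:
        return float(norm.cdf((low - true_stil) / sigma))
    return 0.0
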