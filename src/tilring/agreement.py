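"""Two-way random-effects ANOVA and the ICC(2,1) absolute-agreement estimate.

For a complete n x k grid of scores (n slides, k readers) the balanced
two-way ANOVA yields three mean squares:

    BMS = k * sum_i (m_i - m)^2 / (n - 1)        between slides
    JMS = n * sum_j (m_j - m)^2 / (k - 1)        between readers
    EMS = sum_ij (Y_ij - m_i - m_j + m)^2 / ((n-1)(k-1))   residual

The single-rater absolute-agreement intraclass correlation under the model
in which both readers and slides are random samples is

    ICC(2,1) = (BMS - EMS) / (BMS + (k-1) EMS + (k/n)(JMS - EMS))

i.e. the estimated share of total score variance attributable to true
between-slide (biological) differences; 1 - ICC is the share attributable
to the readers.  Confidence intervals use the Fleiss-Shrout approximation:
a Satterthwaite degrees-of-freedom for the reader+error mixture and
equal-tail F quantiles.

Negative estimates (possible in small samples when readers disagree more
than slides differ) are reported and flagged, never clamped: the population
parameter lives in [0, 1] but silently truncating the estimator would
distort coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .core_io import ScoreMatrix

__all__ = [
    "VarianceComponents",
    "ICCResult",
    "AgreementError",
    "IncompleteDataError",
    "DegenerateVarianceError",
    "anova_decompose",
    "icc_2_1",
    "icc_confidence_interval",
    "icc_report",
]


class AgreementError(ValueError):
    pass


class IncompleteDataError(AgreementError):
    """The grid has missing cells; impute before decomposing."""


class DegenerateVarianceError(AgreementError):
    """All mean squares are zero (constant matrix): the ICC is 0/0."""


@dataclass(frozen=True)
class VarianceComponents:
    """Balanced two-way ANOVA mean squares and degrees of freedom."""

    ms_cases: float  # BMS
    ms_readers: float  # JMS
    ms_error: float  # EMS
    n: int
    k: int

    @property
    def df_cases(self) -> int:
        return self.n - 1

    @property
    def df_readers(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)

    @property
    def var_cases(self) -> float:
        """Method-of-moments slide variance component (BMS - EMS)/k."""
        return (self.ms_cases - self.ms_error) / self.k

    @property
    def var_readers(self) -> float:
        """Reader variance component (JMS - EMS)/n."""
        return (self.ms_readers - self.ms_error) / self.n

    @property
    def var_error(self) -> float:
        return self.ms_error


@dataclass(frozen=True)
class ICCResult:
    """ICC(2,1) point estimate with Fleiss-Shrout confidence bounds."""

    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float = 0.95
    negative_flag: bool = False
    degenerate_ci: bool = False
    n: int = 0
    k: int = 0

    def format(self, digits: int = 2) -> str:
        """Human-readable "estimate (lo-hi)" in the reporting style of
        multi-reader concordance tables."""
        est = f"{self.estimate:.{digits}f}"
        if self.ci_low is None or self.ci_high is None:
            return est
        if self.degenerate_ci:
            return f"{est} (degenerate)"
        return f"{est} ({self.ci_low:.{digits}f}–{self.ci_high:.{digits}f})"

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "negative_flag": self.negative_flag,
            "degenerate_ci": self.degenerate_ci,
            "n_slides": self.n,
            "n_readers": self.k,
            "formatted": self.format(),
        }


def anova_decompose(matrix: ScoreMatrix) -> VarianceComponents:
    """Balanced two-way ANOVA mean squares of a complete score grid."""
    if not matrix.is_complete:
        raise IncompleteDataError(
            f"{matrix.n_missing} missing cells; run impute_missing first"
        )
    n, k = matrix.n_slides, matrix.n_readers
    if n < 2 or k < 2:
        raise AgreementError(f"need at least 2 slides and 2 readers, got {n}x{k}")
    y = matrix.scores
    grand = y.mean()
    slide_means = y.mean(axis=1)
    reader_means = y.mean(axis=0)
    bms = k * np.sum((slide_means - grand) ** 2) / (n - 1)
    jms = n * np.sum((reader_means - grand) ** 2) / (k - 1)
    resid = y - slide_means[:, None] - reader_means[None, :] + grand
    ems = np.sum(resid**2) / ((n - 1) * (k - 1))
    return VarianceComponents(float(bms), float(jms), float(ems), n, k)


def icc_2_1(components: VarianceComponents) -> ICCResult:
    """Point estimate of ICC(2,1) from the ANOVA mean squares."""
    bms, jms, ems = components.ms_cases, components.ms_readers, components.ms_error
    n, k = components.n, components.k
    denom = bms + (k - 1) * ems + (k / n) * (jms - ems)
    if denom == 0:
        raise DegenerateVarianceError("all mean squares are zero; ICC undefined")
    est = (bms - ems) / denom
    return ICCResult(estimate=float(est), negative_flag=bool(est < 0), n=n, k=k)


class ConfidenceInterval(NamedTuple):
    low: float
    high: float
    degenerate: bool


def icc_confidence_interval(
    components: VarianceComponents, estimate: float, level: float = 0.95
) -> ConfidenceInterval:
    """Fleiss-Shrout equal-tail interval for ICC(2,1).

    Uses a Satterthwaite-style fractional df v for the reader-plus-error
    mixture and F quantiles at 1 - alpha/2 in each tail.  When EMS is zero
    (perfect agreement) the F ratio is undefined and the interval collapses
    to the point estimate, flagged degenerate.

    For strongly negative estimates the Satterthwaite df can collapse to
    zero and the F quantiles blow up; any non-finite bound falls back to
    the point estimate and the interval is widened to bracket it, so
    ``low <= estimate <= high`` always holds.
    """
    if not 0 < level < 1:
        raise AgreementError(f"confidence level must be in (0, 1), got {level}")
    bms, jms, ems = components.ms_cases, components.ms_readers, components.ms_error
    n, k = components.n, components.k
    if ems == 0:
        return ConfidenceInterval(estimate, estimate, True)

    fj = jms / ems
    a = k * estimate
    c = n * (1 + (k - 1) * estimate) - k * estimate
    v = (k - 1) * (n - 1) * (a * fj + c) ** 2 / ((n - 1) * a**2 * fj**2 + c**2)
    alpha = 1 - level
    with np.errstate(invalid="ignore", divide="ignore"):
        f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
        low = n * (bms - f_low * ems) / (
            f_low * (k * jms + (k * n - k - n) * ems) + n * bms
        )
        high = n * (f_up * bms - ems) / (
            k * jms + (k * n - k - n) * ems + n * f_up * bms
        )
    if not np.isfinite(low):
        low = estimate
    if not np.isfinite(high):
        high = estimate
    low, high = min(low, estimate), max(high, estimate)
    return ConfidenceInterval(float(low), float(high), False)


def icc_report(matrix: ScoreMatrix, level: float = 0.95) -> ICCResult:
    """Decompose, estimate, and attach the confidence interval."""
    comps = anova_decompose(matrix)
    point = icc_2_1(comps)
    ci = icc_confidence_interval(comps, point.estimate, level)
    return ICCResult(
        estimate=point.estimate,
        ci_low=ci.low,
        ci_high=ci.high,
        level=level,
        negative_flag=point.negative_flag,
        degenerate_ci=ci.degenerate,
        n=comps.n,
        k=comps.k,
    )
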