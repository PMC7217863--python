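"""Cutpoint concordance and the per-slide variability screen.

Clinical use of sTIL scores dichotomizes them at a threshold ("cutpoint"),
so agreement is assessed as the percent of slides on which a pair of
readers lands on the same side of each cutpoint (score >= cutpoint is the
upper class).  Summaries report, per cutpoint, the mean and sample SD of
these pairwise rates over all k(k-1)/2 unordered reader pairs.

The variability screen ranks slides by the SD of their scores across
readers; the top fraction (plus any manually flagged extras) is selected
for qualitative review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import ScoreMatrix

__all__ = [
    "DEFAULT_CUTPOINTS",
    "ConcordanceTable",
    "VariabilityRanking",
    "dichotomize",
    "pair_agreement",
    "concordance_table",
    "slide_variability",
    "select_most_variable",
    "SelectionError",
]

DEFAULT_CUTPOINTS: tuple[float, ...] = (1.0, 5.0, 10.0, 30.0, 75.0)


class SelectionError(ValueError):
    """An extra slide id is unknown or already in the top-fraction set."""


def dichotomize(score, cutpoint: float):
    """True where score >= cutpoint (boundary belongs to the upper class).

    Accepts scalars or arrays; scores must lie in [0, 100].
    """
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("scores must lie in [0, 100]")
    out = arr >= cutpoint
    return bool(out) if np.isscalar(score) else out


def pair_agreement(a, b, cutpoint: float) -> float:
    """Fraction of slides on which two readers agree after dichotomizing."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"score vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.mean(dichotomize(a, cutpoint) == dichotomize(b, cutpoint)))


@dataclass(frozen=True)
class ConcordanceTable:
    """Per-cutpoint pairwise agreement rates with mean/SD summaries."""

    cutpoints: tuple[float, ...]
    reader_ids: tuple[str, ...]
    pair_rates: dict  # cutpoint -> symmetric k x k ndarray, unit diagonal
    mean: dict  # cutpoint -> mean over unordered pairs
    sd: dict  # cutpoint -> sample SD over unordered pairs

    @property
    def n_pairs(self) -> int:
        k = len(self.reader_ids)
        return k * (k - 1) // 2

    def format(self, digits: int = 2) -> str:
        """Per-cutpoint "mean (±SD)" lines, the standard reporting style."""
        lines = []
        for c in self.cutpoints:
            lines.append(
                f"TILs <{c:g} vs ≥{c:g}%  "
                f"{self.mean[c]:.{digits}f} (±{self.sd[c]:.{digits}f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cutpoints": list(self.cutpoints),
            "n_pairs": self.n_pairs,
            "per_cutpoint": {
                f"{c:g}": {"mean": self.mean[c], "sd": self.sd[c]}
                for c in self.cutpoints
            },
        }


def concordance_table(
    matrix: ScoreMatrix, cutpoints=DEFAULT_CUTPOINTS
) -> ConcordanceTable:
    """Pairwise percent agreement over all unordered reader pairs per cutpoint.

    The SD uses the sample (pairs - 1) denominator.
    """
    if not matrix.is_complete:
        raise ValueError("matrix has missing cells; impute first")
    k = matrix.n_readers
    if k < 2:
        raise ValueError("need at least 2 readers")
    cutpoints = tuple(float(c) for c in cutpoints)
    rates: dict = {}
    means: dict = {}
    sds: dict = {}
    for c in cutpoints:
        classes = dichotomize(matrix.scores, c)  # n x k booleans
        # rate[j1,j2] = fraction of slides with matching classes
        agree = classes[:, :, None] == classes[:, None, :]
        grid = agree.mean(axis=0)
        iu = np.triu_indices(k, 1)
        pair_vals = grid[iu]
        rates[c] = grid
        means[c] = float(pair_vals.mean())
        sds[c] = float(pair_vals.std(ddof=1)) if pair_vals.size > 1 else 0.0
    return ConcordanceTable(cutpoints, matrix.reader_ids, rates, means, sds)


@dataclass(frozen=True)
class VariabilityRanking:
    """Per-slide mean and across-reader SD, ranked by SD descending."""

    slide_ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    order: tuple[int, ...]  # indices into slide_ids, highest SD first
    flagged: frozenset = field(default_factory=frozenset)
    extras: frozenset = field(default_factory=frozenset)

    @property
    def n(self) -> int:
        return len(self.slide_ids)

    def rank_of(self, slide_id: str) -> int:
        """1-based rank by descending SD (ties broken by slide id)."""
        return self.order.index(self.slide_ids.index(slide_id)) + 1


def slide_variability(matrix: ScoreMatrix) -> VariabilityRanking:
    """Mean and sample SD (k-1 denominator) of each slide's scores across readers."""
    if not matrix.is_complete:
        raise ValueError("matrix has missing cells; impute first")
    if matrix.n_readers < 2:
        raise ValueError("need at least 2 readers")
    means = matrix.scores.mean(axis=1)
    sds = matrix.scores.std(axis=1, ddof=1)
    # descending SD, ties broken by slide id ascending — deterministic
    order = sorted(range(matrix.n_slides),
                   key=lambda i: (-sds[i], matrix.slide_ids[i]))
    return VariabilityRanking(matrix.slide_ids, means, sds, tuple(order))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_most_variable(
    ranking: VariabilityRanking, fraction: float = 0.10, extras=()
) -> VariabilityRanking:
    """Flag the top-``fraction`` highest-SD slides plus manually chosen extras.

    The count is round(fraction * n) half-away-from-zero, minimum 1.  Extras
    must exist in the study and must not already be in the top-fraction set.
    Returns a copy of the ranking with ``flagged`` and ``extras`` filled.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_top = max(1, _round_half_away(fraction * ranking.n))
    top = frozenset(ranking.slide_ids[i] for i in ranking.order[:n_top])
    extras = tuple(extras)
    known = set(ranking.slide_ids)
    for sid in extras:
        if sid not in known:
            raise SelectionError(f"unknown extra slide id {sid!r}")
        if sid in top:
            raise SelectionError(f"extra slide {sid!r} already in the top-{fraction:g} set")
    if len(set(extras)) != len(extras):
        raise SelectionError("duplicate extra slide ids")
    return replace(ranking, flagged=top | set(extras), extras=frozenset(extras))
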