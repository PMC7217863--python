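"""Score-matrix data model, delimited-text I/O, validation, and missing-score imputation.

A ring study produces a slides x readers grid of percent sTIL scores
(0-100).  The canonical interchange format is long CSV with columns
``slide_id,reader_id,score``; a wide layout (one row per slide, one column
per reader) is accepted for convenience.  Missing scores are encoded by an
absent row or an empty score field (long) or an empty cell (wide) -- never
by sentinel values.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScoreMatrix",
    "ValidationReport",
    "ScoreDataError",
    "ParseError",
    "DuplicateEntryError",
    "ImputationError",
    "read_scores",
    "write_scores",
    "validate",
    "impute_missing",
]


class ScoreDataError(ValueError):
    """Base class for score-table errors."""


class ParseError(ScoreDataError):
    """A row could not be parsed (malformed or non-numeric score)."""


class DuplicateEntryError(ScoreDataError):
    """The same (slide, reader) pair appeared more than once."""


class ImputationError(ScoreDataError):
    """A slide has no observed score to impute from."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Slides x readers grid of percent sTIL scores.

    Missing cells are NaN in ``scores``; ``mask`` exposes them as booleans.
    Slide and reader order is the order of first appearance in the source.
    """

    slide_ids: tuple[str, ...]
    reader_ids: tuple[str, ...]
    scores: np.ndarray  # float64, shape (n_slides, n_readers), NaN = missing
    study_label: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape != (len(self.slide_ids), len(self.reader_ids)):
            raise ScoreDataError(
                f"score grid shape {scores.shape} does not match "
                f"{len(self.slide_ids)} slides x {len(self.reader_ids)} readers"
            )
        if len(set(self.slide_ids)) != len(self.slide_ids):
            raise ScoreDataError("slide_ids are not unique")
        if len(set(self.reader_ids)) != len(self.reader_ids):
            raise ScoreDataError("reader_ids are not unique")

    @property
    def n_slides(self) -> int:
        return len(self.slide_ids)

    @property
    def n_readers(self) -> int:
        return len(self.reader_ids)

    @property
    def mask(self) -> np.ndarray:
        """Boolean missing-cell mask (True where the score is absent)."""
        return np.isnan(self.scores)

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    @property
    def is_complete(self) -> bool:
        return not self.mask.any()

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame indexed by slide_id with one column per reader."""
        return pd.DataFrame(self.scores, index=list(self.slide_ids),
                            columns=list(self.reader_ids))

    def equals(self, other: "ScoreMatrix") -> bool:
        return (
            self.slide_ids == other.slide_ids
            and self.reader_ids == other.reader_ids
            and np.array_equal(self.scores, other.scores, equal_nan=True)
        )


@dataclass(frozen=True)
class ValidationReport:
    n_slides: int
    n_readers: int
    n_missing: int
    out_of_range: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.out_of_range

    def to_dict(self) -> dict:
        return {
            "n_slides": self.n_slides,
            "n_readers": self.n_readers,
            "n_missing": self.n_missing,
            "out_of_range": [list(t) for t in self.out_of_range],
            "ok": self.ok,
        }


def _format_score(x: float) -> str:
    # repr of a Python float is shortest round-trippable form
    return repr(float(x))


def read_scores(path, layout: str = "long") -> ScoreMatrix:
    """Read a score table from CSV.

    Parameters
    ----------
    path : str or path-like
    layout : {"long", "wide"}
        Long: header ``slide_id,reader_id,score``, one row per observed
        score; absent pairs are missing.  Wide: first column slide ids,
        remaining columns one per reader; empty cells are missing.
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_scores(fh, layout, name=str(path))


def _parse_scores(fh, layout: str, name: str = "<stream>") -> ScoreMatrix:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError(f"{name}: empty file") from None

    if layout == "long":
        if len(header) < 3:
            raise ParseError(f"{name}:1: expected columns slide_id,reader_id,score")
        slides: list[str] = []
        readers: list[str] = []
        seen: dict[tuple[str, str], float] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(f"{name}:{lineno}: expected 3 fields, got {len(row)}")
            sid, rid, raw = row[0], row[1], row[2].strip()
            if raw == "":
                score = np.nan  # declared-missing pair; pins id ordering
            else:
                try:
                    score = float(raw)
                except ValueError:
                    raise ParseError(
                        f"{name}:{lineno}: non-numeric score {raw!r} for ({sid}, {rid})"
                    ) from None
            if (sid, rid) in seen:
                raise DuplicateEntryError(
                    f"{name}:{lineno}: duplicate entry for slide {sid!r}, reader {rid!r}"
                )
            seen[(sid, rid)] = score
            if sid not in slides:
                slides.append(sid)
            if rid not in readers:
                readers.append(rid)
        grid = np.full((len(slides), len(readers)), np.nan)
        r_index = {r: j for j, r in enumerate(readers)}
        s_index = {s: i for i, s in enumerate(slides)}
        for (sid, rid), score in seen.items():
            grid[s_index[sid], r_index[rid]] = score
        return ScoreMatrix(tuple(slides), tuple(readers), grid)

    # wide
    if len(header) < 2:
        raise ParseError(f"{name}:1: wide layout needs slide_id plus reader columns")
    reader_ids = tuple(header[1:])
    slides = []
    rows = []
    seen_slides: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{name}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        sid = row[0]
        if sid in seen_slides:
            raise DuplicateEntryError(f"{name}:{lineno}: duplicate slide {sid!r}")
        seen_slides.add(sid)
        vals = []
        for rid, raw in zip(reader_ids, row[1:]):
            raw = raw.strip()
            if raw == "":
                vals.append(np.nan)
                continue
            try:
                vals.append(float(raw))
            except ValueError:
                raise ParseError(
                    f"{name}:{lineno}: non-numeric score {raw!r} for ({sid}, {rid})"
                ) from None
        slides.append(sid)
        rows.append(vals)
    grid = np.asarray(rows, dtype=float) if rows else np.empty((0, len(reader_ids)))
    return ScoreMatrix(tuple(slides), reader_ids, grid)


def write_scores(matrix: ScoreMatrix, path, layout: str = "long") -> None:
    """Write a score table as CSV; ``read_scores`` round-trips it exactly."""
    if layout not in ("long", "wide"):
        raise ValueError(f"unknown layout {layout!r}")
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    if layout == "long":
        writer.writerow(["slide_id", "reader_id", "score"])
        for i, sid in enumerate(matrix.slide_ids):
            for j, rid in enumerate(matrix.reader_ids):
                v = matrix.scores[i, j]
                # missing cells are written with an empty score field so the
                # reader/slide appearance order survives the round trip
                writer.writerow([sid, rid, "" if np.isnan(v) else _format_score(v)])
    else:
        writer.writerow(["slide_id", *matrix.reader_ids])
        for i, sid in enumerate(matrix.slide_ids):
            row = [sid]
            for v in matrix.scores[i]:
                row.append("" if np.isnan(v) else _format_score(v))
            writer.writerow(row)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def validate(matrix: ScoreMatrix) -> ValidationReport:
    """Report-only check: counts missing cells and lists scores outside [0, 100]."""
    bad = []
    for i, sid in enumerate(matrix.slide_ids):
        for j, rid in enumerate(matrix.reader_ids):
            v = matrix.scores[i, j]
            if not np.isnan(v) and not (0.0 <= v <= 100.0):
                bad.append((sid, rid, float(v)))
    return ValidationReport(
        n_slides=matrix.n_slides,
        n_readers=matrix.n_readers,
        n_missing=matrix.n_missing,
        out_of_range=tuple(bad),
    )


def impute_missing(matrix: ScoreMatrix) -> ScoreMatrix:
    """Replace each missing cell by the mean of that slide's observed scores.

    This is the ring-study rule for sporadic missing reads: a slide missing
    one of its 32 scores gets the mean of the 31 remaining.  Observed cells
    are untouched; a matrix with no missing cells is returned unchanged.
    """
    if matrix.is_complete:
        return matrix
    scores = matrix.scores.copy()
    for i, sid in enumerate(matrix.slide_ids):
        row = scores[i]
        missing = np.isnan(row)
        if not missing.any():
            continue
        if missing.all():
            raise ImputationError(f"slide {sid!r} has no observed scores to impute from")
        row[missing] = row[~missing].mean()
    return replace(matrix, scores=scores)
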