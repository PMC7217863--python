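"""Full-study report: validation, ICC, concordance, variability screen.

Composes every pipeline stage over one score table and writes a bundle:
a machine-readable JSON, a per-slide variability CSV, a mean-vs-SD scatter
(SVG), and a human-readable text summary.  Outputs are deterministic for a
given input; on any stage failure partial outputs are removed.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import matplotlib
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .agreement import icc_report
from .concordance import (
    DEFAULT_CUTPOINTS,
    concordance_table,
    select_most_variable,
    slide_variability,
)
from .core_io import impute_missing, read_scores, validate

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

log = logging.getLogger("tilring")

REPORT_SCHEMA_VERSION = 1

__all__ = ["StudyConfig", "run_report"]


class StudyConfig(BaseModel):
    """Configuration for one end-to-end study report."""

    input_path: str
    layout: str = "long"
    impute: bool = True
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    variability_fraction: float = Field(default=0.10, gt=0, le=1)
    extras: tuple[str, ...] = ()
    level: float = Field(default=0.95, gt=0, lt=1)
    output_dir: str = "report"

    @field_validator("cutpoints")
    @classmethod
    def _check_cutpoints(cls, v):
        if any(not 0 < c < 100 for c in v):
            raise ValueError("cutpoints must lie in (0, 100)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        return v


def _write_variability_csv(path: Path, ranking) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["slide_id", "mean", "sd", "rank", "flagged"])
        for rank, idx in enumerate(ranking.order, start=1):
            sid = ranking.slide_ids[idx]
            writer.writerow([
                sid,
                repr(float(ranking.means[idx])),
                repr(float(ranking.sds[idx])),
                rank,
                int(sid in ranking.flagged),
            ])


def _write_scatter(path: Path, ranking) -> None:
    with plt.rc_context({"svg.hashsalt": "tilring"}):
        fig, ax = plt.subplots(figsize=(5, 4))
        flagged = [sid in ranking.flagged for sid in ranking.slide_ids]
        plain = [not f for f in flagged]
        ax.scatter(ranking.means[plain], ranking.sds[plain],
                   s=18, c="tab:blue", label="slides")
        if any(flagged):
            ax.scatter(ranking.means[flagged], ranking.sds[flagged],
                       s=30, c="tab:red", marker="s", label="flagged")
            ax.legend()
        ax.set_xlabel("mean sTIL score (%)")
        ax.set_ylabel("SD across readers (%)")
        ax.set_title("Per-slide scoring variability")
        fig.tight_layout()
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)


def run_report(config: StudyConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the report dictionary (also written as ``report.json``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        log.info("reading %s (%s layout)", config.input_path, config.layout)
        matrix = read_scores(config.input_path, config.layout)
        report_val = validate(matrix)
        if not report_val.ok:
            raise ValueError(
                f"validation failed: {len(report_val.out_of_range)} out-of-range scores"
            )
        if config.impute and not matrix.is_complete:
            log.info("imputing %d missing cells by per-slide means", matrix.n_missing)
            matrix = impute_missing(matrix)

        log.info("ICC(2,1) with %.0f%% Fleiss–Shrout interval", 100 * config.level)
        icc = icc_report(matrix, level=config.level)
        log.info("ICC %s", icc.format())

        table = concordance_table(matrix, config.cutpoints)
        ranking = slide_variability(matrix)
        ranking = select_most_variable(
            ranking, config.variability_fraction, config.extras
        )
        log.info("flagged %d slides for review", len(ranking.flagged))

        csv_path = outdir / "variability.csv"
        _write_variability_csv(csv_path, ranking)
        written.append(csv_path)
        svg_path = outdir / "variability_scatter.svg"
        _write_scatter(svg_path, ranking)
        written.append(svg_path)

        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "tilring_version": __version__,
            "input": {"path": str(config.input_path), "layout": config.layout,
                      "imputed": bool(config.impute)},
            "validation": report_val.to_dict(),
            "icc": icc.to_dict(),
            "concordance": table.to_dict(),
            "variability": {
                "fraction": config.variability_fraction,
                "extras": sorted(config.extras),
                "flagged": sorted(ranking.flagged),
                "n_flagged": len(ranking.flagged),
            },
        }
        json_path = outdir / "report.json"
        json_path.write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(json_path)

        txt_path = outdir / "report.txt"
        txt_path.write_text(
            "\n".join([
                f"Study report ({matrix.n_slides} slides x {matrix.n_readers} readers,"
                f" {report_val.n_missing} missing scores)",
                f"ICC(2,1): {icc.format()}",
                "Concordance rates (mean (±SD) over reader pairs):",
                table.format(),
                f"Flagged for review ({len(ranking.flagged)}): "
                + ", ".join(sorted(ranking.flagged)),
                "",
            ]),
            encoding="utf-8",
        )
        written.append(txt_path)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
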