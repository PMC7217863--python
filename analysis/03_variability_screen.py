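"""Per-slide variability screen: top-10% SD plus manually flagged extras.

For each study, ranks slides by the SD of their scores across readers,
flags the top 10% (6, 6, and 10 slides), then adds the manual extras
(1, 0, 3) — here the next-most-variable unflagged slides, standing in for
the expert's hand-picked cases.  Writes a ranking CSV and a mean-vs-SD
scatter (SVG) per study; the flagged totals are 7 + 6 + 13 = 26 slides.
"""

import csv

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from studies import N_EXTRAS, RESULTS, RING_STUDIES, study_csv
from tilring.concordance import select_most_variable, slide_variability
from tilring.core_io import impute_missing, read_scores

total = 0
for name in RING_STUDIES:
    matrix = impute_missing(read_scores(study_csv(name), "long"))
    ranking = slide_variability(matrix)
    n_top = round(0.10 * ranking.n)
    top = {ranking.slide_ids[i] for i in ranking.order[:n_top]}
    extras = [ranking.slide_ids[i] for i in ranking.order
              if ranking.slide_ids[i] not in top][: N_EXTRAS[name]]
    ranking = select_most_variable(ranking, 0.10, extras)
    total += len(ranking.flagged)

    with open(RESULTS / f"{name.lower()}_variability.csv", "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["slide_id", "mean", "sd", "rank", "flagged", "extra"])
        for rank, idx in enumerate(ranking.order, start=1):
            sid = ranking.slide_ids[idx]
            writer.writerow([sid, f"{ranking.means[idx]:.4f}",
                             f"{ranking.sds[idx]:.4f}", rank,
                             int(sid in ranking.flagged),
                             int(sid in ranking.extras)])

    fig, ax = plt.subplots(figsize=(5, 4))
    plain = [s not in ranking.flagged for s in ranking.slide_ids]
    in_top = [s in top for s in ranking.slide_ids]
    in_extra = [s in ranking.extras for s in ranking.slide_ids]
    ax.scatter(ranking.means[plain], ranking.sds[plain], s=16, c="tab:blue")
    ax.scatter(ranking.means[in_top], ranking.sds[in_top], s=30, c="tab:red",
               marker="s", label="top 10% SD")
    if any(in_extra):
        ax.scatter(ranking.means[in_extra], ranking.sds[in_extra], s=40,
                   c="black", marker="^", label="manual extras")
    ax.set_xlabel("mean sTIL score (%)")
    ax.set_ylabel("SD across readers (%)")
    ax.set_title(f"{name}: per-slide scoring variability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / f"{name.lower()}_variability.svg")
    plt.close(fig)

    print(f"{name}: {n_top} top-SD slides + {len(extras)} extras "
          f"= {len(ranking.flagged)} flagged")

print(f"total flagged for review across studies: {total}")
assert total == 26
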