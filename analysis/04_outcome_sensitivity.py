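"""Clinical consequences of scoring deviations.

Two questions, answered with the illustrative prognostic model (calibrated
to give a 76% 5-year iDFS at 30% sTILs for the reference patient):

1. How much does the estimated 5-year iDFS move if a pathologist mis-scores
   a true 30%-sTIL tumor by ±5, ±10, ±20 points?  (Answer: modestly —
   roughly 1.5 points of iDFS per 5 sTIL points near the reference.)
2. How often does scoring noise flip a patient across a treatment cutpoint,
   and how much does an indeterminate zone around the cutpoint help?

Writes results/outcome_sensitivity.json and results/misassignment.csv.
"""

import csv
import json

from studies import RESULTS
from tilring.sensitivity import (
    deviation_grid,
    illustrative_model,
    misassignment_probability,
    zone_misassignment_probability,
)

model = illustrative_model()  # baseline_cumhaz=0.274, hr_per_10=0.87
grid = deviation_grid(model, true_stil=30.0,
                      deltas=(-20.0, -10.0, -5.0, 0.0, 5.0, 10.0, 20.0))
(RESULTS / "outcome_sensitivity.json").write_text(
    json.dumps(grid.to_dict(), indent=2, sort_keys=True) + "\n")

print(f"true sTILs 30%: 5-year iDFS {100 * grid.true_outcome:.1f}%")
for row in grid.rows:
    print(f"  scored {row.stil:5.1f}% (delta {row.delta:+5.1f}): "
          f"iDFS {100 * row.outcome:.1f}% "
          f"({100 * row.outcome_delta:+.1f} points)")

# misassignment at the 30% cutpoint vs an indeterminate 25-35% band,
# for scoring noise typical of a flagged high-variability slide
rows = []
for true in (20.0, 25.0, 28.0, 30.0, 32.0, 35.0, 40.0):
    for sigma in (4.0, 8.0, 15.0):
        rows.append({
            "true_stil": true,
            "sigma": sigma,
            "single_cutpoint_30": round(
                misassignment_probability(true, sigma, 30.0), 4),
            "zone_25_35": round(
                zone_misassignment_probability(true, sigma, 25.0, 35.0), 4),
        })
with open(RESULTS / "misassignment.csv", "w", newline="") as fh:
    writer = csv.DictWriter(fh, fieldnames=list(rows[0]), lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)

worst = max(rows, key=lambda r: r["single_cutpoint_30"])
print(f"\nworst single-cutpoint misassignment in the sweep: "
      f"{worst['single_cutpoint_30']:.0%} at true {worst['true_stil']}%, "
      f"sigma {worst['sigma']}; the 25-35 indeterminate zone cuts it to "
      f"{worst['zone_25_35']:.0%}")
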