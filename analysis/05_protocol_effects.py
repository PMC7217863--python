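"""Why the anchored multi-region protocol agrees better, in silico.

Holding all else fixed, sweeps (a) the number of 1 mm^2 regions averaged
per slide (m = 1, 3, 10) with within-slide heterogeneity present, and
(b) the reader-bias SD (10 -> 5 -> 0, emulating progressively stronger
reference-image anchoring).  Both protocol changes should monotonically
raise the mean estimated ICC over 200 replicate studies.

Writes results/protocol_effects.csv.
"""

import csv

from studies import RESULTS
from tilring.simstudies import reader_bias_study, region_averaging_study

regions = region_averaging_study(m_values=(1, 3, 10), n_replicates=200,
                                 seed=2025, var_region=150.0)
bias = reader_bias_study(sigma_readers=(10.0, 5.0, 0.0), n_replicates=200,
                         seed=2026)

rows = [{"sweep": "regions_averaged", "setting": m, "mean_icc": f"{v:.4f}"}
        for m, v in regions.items()]
rows += [{"sweep": "reader_bias_sd", "setting": sd, "mean_icc": f"{v:.4f}"}
         for sd, v in bias.items()]
with open(RESULTS / "protocol_effects.csv", "w", newline="") as fh:
    writer = csv.DictWriter(fh, fieldnames=list(rows[0]), lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)

print("regions averaged per slide -> mean ICC:",
      {m: round(v, 3) for m, v in regions.items()})
print("reader-bias SD -> mean ICC:",
      {sd: round(v, 3) for sd, v in bias.items()})
assert regions[1] < regions[3] < regions[10]
assert bias[10.0] < bias[5.0] < bias[0.0]
print("both protocol effects are monotone, matching the field observation "
      "that multi-region averaging and reference anchoring improve agreement")
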