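# tilring

Reader-concordance analysis for stromal tumor-infiltrating lymphocyte
(sTIL) ring studies.

sTILs — the percentage of intratumoral stromal area occupied by mononuclear
immune cells — are prognostic and predictive biomarkers in triple-negative
and HER2-positive breast cancer, scored visually by pathologists on a
0–100% scale. Before such a score can drive treatment decisions, its
reproducibility across pathologists has to be quantified. This package
implements the statistics of a multi-reader ("ring") concordance study for
anyone running or re-analysing one:

- **Agreement**: balanced two-way random-effects ANOVA and the single-rater
  absolute-agreement intraclass correlation
  `ICC(2,1) = (BMS − EMS) / (BMS + (k−1)EMS + (k/n)(JMS − EMS))`,
  with Fleiss–Shrout approximate confidence intervals. ICC is the share of
  score variance attributable to real biological differences between
  slides; 1 − ICC is the share attributable to the readers.
- **Cutpoint concordance**: pairwise percent agreement after dichotomizing
  at clinical cutpoints (1, 5, 10, 30, 75%), summarised as mean (±SD) over
  all reader pairs.
- **Variability screen**: per-slide SD across readers, ranked, with
  top-10% (plus manual extras) flagging for slide review.
- **Outcome sensitivity**: propagation of scoring deviations through a
  pluggable prognostic model, Gaussian cutpoint-misassignment
  probabilities, and the indeterminate-zone (below X / above Y / in
  between) strategy.
- **Simulator**: a seeded two-way random-effects ring-study generator
  (slide truths, reader biases, within-slide region heterogeneity averaged
  over m regions, residual noise, rounding, missingness), since real
  ring-study scores are usually restricted for patient privacy.

## Worked example

Simulate a 60-slide × 6-reader study, then estimate agreement:

```python
import tilring as tr

cfg = tr.SimulationConfig(n_slides=60, n_readers=6, missing_rate=0.01, seed=7)
matrix, truth = tr.simulate_study(cfg)
print(f"population ICC: {truth.population_icc:.3f}")

matrix = tr.impute_missing(matrix)          # per-slide mean imputation
print("ICC(2,1):", tr.icc_report(matrix).format())
print(tr.concordance_table(matrix).format())
```

prints

```
population ICC: 0.677
ICC(2,1): 0.73 (0.63–0.81)
TILs <1 vs ≥1%  0.89 (±0.04)
TILs <5 vs ≥5%  0.84 (±0.06)
TILs <10 vs ≥10%  0.79 (±0.05)
TILs <30 vs ≥30%  0.76 (±0.05)
TILs <75 vs ≥75%  0.95 (±0.02)
```

The estimated ICC of 0.73 (interval 0.63–0.81) brackets the generative
truth of 0.68: about 70% of score variance reflects real differences
between slides, the rest the readers. Concordance is weakest at the
mid-range cutpoints (10–30%), where the right-skewed score distribution
piles up, and high at the sparse 75% cutpoint — dichotomizing near a
crowded threshold is fragile no matter how good the readers are.

Outcome sensitivity for a reference patient truly at 30% sTILs, whose
5-year invasive disease-free survival (iDFS) the illustrative model puts at
76%:

```python
model = tr.illustrative_model()             # synthetic calibration
grid = tr.deviation_grid(model, true_stil=30, deltas=(-10, 0, 10))
for row in grid.rows:
    print(f"scored {row.stil:.0f}%: iDFS {100 * row.outcome:.0f}%")
```

```
scored 20%: iDFS 73%
scored 30%: iDFS 76%
scored 40%: iDFS 79%
```

A ±10-point scoring error moves the estimate by ~3 points — modest
prognostically, but `tr.misassignment_probability(24, 8, 30)` ≈ 0.23 shows
how often that much noise flips a patient truly at 24% across a 30%
treatment cutpoint; with a 25–35% indeterminate zone only confident wrong
calls remain, and `tr.zone_misassignment_probability(24, 8, 25, 35)` ≈ 0.08.

## Command line

```bash
tilring simulate --n-slides 60 --n-readers 28 --seed 1 --out scores.csv
tilring icc --input scores.csv --level 0.95
tilring concordance --input scores.csv --cutpoints 1,5,10,30,75
tilring variability --input scores.csv --fraction 0.10
tilring sensitivity --true-stil 30 --deltas 5,10,20
tilring misassign --true-stil 28 --sigma 8 --cutpoint 30 --band 20:40
tilring report --input scores.csv --out-dir report/
```

JSON goes to stdout, logs to stderr, and `report` writes a full bundle
(validation, ICC, concordance table, variability ranking CSV + SVG
scatter, machine-readable JSON).

## Analysis scripts

`analysis/` contains the narrative pipeline over three synthetic ring
studies that emulate the published study designs (60×32 with sporadic
missing scores; 60×28 with three regions averaged and anchored readers;
100×6 whole sections):

```bash
python analysis/01_simulate_ring_studies.py   # generate the studies
python analysis/02_reader_agreement.py        # ICC + concordance table
python analysis/03_variability_screen.py      # top-10% SD + extras = 26 slides
python analysis/04_outcome_sensitivity.py     # iDFS deviations, misassignment
python analysis/05_protocol_effects.py        # why multi-region + anchoring win
```

Outputs land in `results/`. Scripts 02–05 expect 01 to have run first.

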