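# Methods

## Problem

Stromal tumor-infiltrating lymphocytes (sTILs) are scored by pathologists as
the percentage of intratumoral stromal area occupied by mononuclear immune
cells, 0–100. Multi-reader "ring" studies — many pathologists independently
scoring the same slides — quantify how reproducible that visual estimate is.
This package implements the statistical machinery of such an analysis:
agreement estimation, cutpoint concordance, a per-slide variability screen,
and propagation of scoring error into outcome estimates. Because raw ring-
study scores are typically restricted for patient privacy, the package also
ships a generator that simulates studies with the structure the analysis
assumes, so every stage is testable end to end.

## Data model and imputation

Scores live in a slides × readers grid (`ScoreMatrix`) with an explicit
missing mask. The canonical file format is long CSV
(`slide_id,reader_id,score`); wide CSV is accepted. Missing scores are
encoded as an absent row or an empty score field (long) or an empty cell
(wide) — no sentinel values. The writer always emits one row per cell, using
an empty score field for missing cells: encoding missing purely by absent
rows cannot preserve first-appearance id ordering through a round trip (if
only (s1,r2) and (s2,r1) are observed, no row order yields both id
orderings), and exact round-tripping is a contract here. Scores are floats;
validation reports out-of-range values but never clamps them — downstream
operations refuse invalid matrices instead.

Sporadic missing scores are imputed by the mean of the slide's observed
scores (the rule used when a handful of reads are absent in a balanced
study: a slide missing one of 32 reads gets the mean of the remaining 31).
Imputation is per-slide, idempotent, and leaves each slide's observed mean
unchanged. A per-reader alternative is deliberately not offered. Imputation
runs before any agreement computation, uniformly, because the balanced
ANOVA identities require a complete grid.

## Agreement: ICC(2,1) with Fleiss–Shrout intervals

With grand mean m, slide means m_i and reader means m_j, the balanced
two-way ANOVA mean squares are

    BMS = k Σ(m_i − m)² / (n−1)
    JMS = n Σ(m_j − m)² / (k−1)
    EMS = Σ(Y_ij − m_i − m_j + m)² / ((n−1)(k−1))

and the single-rater, absolute-agreement intraclass correlation under the
two-way random-effects model (both readers and slides random) is

    ICC(2,1) = (BMS − EMS) / (BMS + (k−1) EMS + (k/n)(JMS − EMS)),

algebraically equal to σ̂²_case / (σ̂²_case + σ̂²_reader + σ̂²_error) with the
method-of-moments components σ̂²_case = (BMS−EMS)/k, σ̂²_reader = (JMS−EMS)/n,
σ̂²_error = EMS. ICC is the share of score variance attributable to true
biological differences between slides; 1 − ICC is the reader-attributable
share. The estimator is location- and positive-scale-invariant and is *not*
truncated at zero: small samples with discordant readers can produce
negative estimates, which are reported with `negative_flag` set, because
silent clamping would distort the coverage properties verified below.

Confidence intervals follow the Fleiss–Shrout approximation: with
F_J = JMS/EMS, a = k·ICC and c = n(1+(k−1)ICC) − k·ICC, the Satterthwaite
degrees of freedom are

    v = (k−1)(n−1) (a F_J + c)² / ((n−1) a² F_J² + c²)

used fractionally (no rounding), and with F_L = F(1−α/2; n−1, v),
F_U = F(1−α/2; v, n−1):

    lower = n(BMS − F_L·EMS) / (F_L(k·JMS + (kn−k−n)EMS) + n·BMS)
    upper = n(F_U·BMS − EMS) / (k·JMS + (kn−k−n)EMS + n·F_U·BMS)

Equal tails, α/2 per side, default level 0.95. Numerical handling: EMS = 0
(perfect agreement) makes F_J undefined, so the interval collapses to the
point estimate and is flagged degenerate; for strongly negative estimates
the Satterthwaite df can collapse and produce non-finite quantiles, in which
case the affected bound falls back to the point estimate and the interval is
widened to bracket it. The formulas are validated two ways rather than taken
on faith: against pingouin's independent ICC(A,1) implementation on a fixed
matrix, and by an empirical coverage study (94–95% observed at nominal 95%
for n=60, k=6, population ICC 0.75, 2000 replicates).

## Cutpoint concordance and the variability screen

Scores are dichotomized at clinically used cutpoints (default 1, 5, 10, 30,
75%), with the boundary in the upper class (score ≥ cutpoint). Pairwise
concordance is the fraction of slides on which two readers agree after
dichotomizing; the summary per cutpoint is the mean and sample SD (pairs−1
denominator) over all k(k−1)/2 unordered pairs. With a right-skewed score
distribution, concordance is lowest at cutpoints near the density mode
(5–30%) and high in the sparse 75% tail — classification near a crowded
threshold is intrinsically fragile.

The variability screen computes each slide's mean and sample SD (k−1) across
readers and ranks by SD descending, ties broken by slide id for determinism.
`select_most_variable` flags the top round(fraction·n) slides
(half-away-from-zero, minimum 1 — a convention exact for the 60→6 and
100→10 cases; whether the original analyses rounded, floored or ceiled is
indeterminable since all conventions agree at those sizes) and then adds
manually specified extras, which must exist and not already be flagged. The
downstream review of flagged slides is human histology work, out of scope.

## Outcome sensitivity and misassignment

`PrognosticModel` is a contract: (horizon_years, sTIL %) → event-free
survival probability. The built-in `illustrative_model` is an exponential
proportional-hazards stand-in,

    S(t, s) = exp(−Λ₀ · (t/5) · HR^((s−30)/10)),

with defaults Λ₀ = 0.274 (5-year cumulative hazard at the 30%-sTIL
reference) and HR = 0.87 per +10 sTIL points. These defaults are a
reverse-engineered calibration chosen so the whole-percent 5-year iDFS at
sTILs 30/20/40 reads 76/73/79 — the behaviour of published pooled-trial
prognosis calculators for a reference early-TNBC patient — and the model is
labelled synthetic in its descriptor. It is not a fitted clinical model: the
real pooled-trial Cox coefficients and covariate handling (age, grade, size,
nodes, therapy) are external to this package, and whether sTILs enter such
models linearly on the log-hazard is our modelling choice here, not an
established fact. Display rounding is to the nearest whole percent.

`deviation_grid` evaluates the model at the true score and at signed
deviations (default ±5, ±10, ±20), refusing deviations that leave [0, 100]
rather than clamping. Misassignment treats the observed score as
true + N(0, σ²) — unbiased Gaussian scoring noise, with σ naturally taken
from a flagged slide's inter-reader SD — and returns the probability of
landing on the wrong side of a cutpoint: exactly 0.5 when the truth sits on
the cutpoint, decaying with |true − cutpoint|/σ. The indeterminate-zone
variant classifies below/indeterminate/above against a (low, high) band and
counts only confident-wrong calls (truly below, observed ≥ high, or truly
above, observed < low); widening a band that contains the cutpoint can only
reduce it.

## Synthetic ring studies

The generator draws

    Y_ij = clip₀₁₀₀( snap_q( μ_i + b_j + (1/m) Σ_r z_ijr + e_ij ) )

with slide truths μ_i from a configurable case distribution, reader biases
b_j ~ N(0, σ²_reader), region deviations z_ijr ~ N(0, σ²_region) sampled
independently per reader and averaged over m regions, and residual noise
e_ij ~ N(0, σ²_error). Optional snapping to a rounding grid (5 or 10 mimics
pathologist granularity; default off) precedes clipping; the sporadic
missing mask is applied last and never empties a slide. A single seed drives
split substreams (cases, biases, regions, noise, missingness), so output is
bit-reproducible and changing one component's parameters does not perturb
the others' draws. The implied population ICC,

    Var(μ) / (Var(μ) + σ²_reader + σ²_region/m + σ²_error),

is computed from the configured variances before rounding/clipping and
carried in the truth sidecar.

Defaults emulate the first ring study's design: 60 slides × 32 readers,
case distribution Beta(0.8, 2.6) scaled to 0–100 (right-skewed, mean ≈ 24%,
variance ≈ 409 — typical of breast-cancer sTIL cohorts, and the skew is what
makes cutpoint concordance interesting), σ_reader = 5, σ_region = 11 with
m = 1, σ_error = 7, all in percent units. No empirical variance components
were ever published for the original studies, so these are fixed plausible
stand-ins chosen once; they put the population ICC at ≈ 0.68, the regime the
published ICCs (≈ 0.7) occupy. Reader bias is additive and homoscedastic —
no reader × case interaction beyond region sampling — the simplest model
consistent with the two-way random-effects analysis.

A `clip` flag (default on) lets model-validation studies disable boundary
clipping: the coverage and recovery studies run the pure Gaussian two-way
model (case mean 50, far from the boundaries), because truncation at 0/100
is not part of the model whose interval coverage is being verified. Heavy
clipping of a default-configured study biases the ICC slightly; recovery
tests therefore use configurations with negligible saturation.

What the generator does **not** emulate: spatial structure (regions are
abstract draws, not geometry), reader × case interactions, scanner or
staining artifacts, non-Gaussian reader idiosyncrasies, and informative
missingness. Passing tests therefore demonstrate the statistical machinery
is correct under the stated model, not that real pathologists behave like
the model.

## Monte-Carlo study sizes

The validation studies use 2000 replicates for interval coverage (binomial
SE ≈ 0.5 points at 95%) and 200 replicates for recovery and the protocol
sweeps (SE of a mean ICC ≈ 0.003 at n=60, k=6), sizes at which the checked
effects are far larger than Monte-Carlo error. Protocol sweeps hold
σ²_region = 150 (m = 1, 3, 10) and sweep σ_reader ∈ {10, 5, 0}; both trends
— more regions averaged, less reader bias — raise the mean estimated ICC,
the in-silico counterpart of why an anchored multi-region protocol agrees
best.

## Known limitations

- The Fleiss–Shrout interval is approximate; observed coverage at the
  reference configuration is ~94.5%, slightly conservative-of-nominal, which
  matches its reputation rather than contradicting it.
- Mean imputation slightly understates within-slide variance; with the
  sporadic missingness emulated here (≈ 0.3% of cells) the effect is
  negligible, but the package does not model informative missingness.
- The illustrative prognostic model is for demonstrating sensitivity
  mechanics only; any clinical use requires plugging in a real, validated
  model behind the `PrognosticModel` contract.
- No other agreement coefficients (ICC(1,1), ICC(3,1), average-rater forms,
  kappa, Krippendorff's alpha) and no REML/mixed-model estimation: the
  balanced moment estimators are the analysis this package reproduces.
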