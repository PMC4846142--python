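# Methods

## Disease designation

The ground truth is a veterinary lesion grade on a 0–5 scale in 0.5 steps
(multi-examiner averages). Status is a total function of the grade:
healthy below 1 (a 0.5 — minimal, subtle lesions — still counts healthy),
diseased at 1 or above. `classify_status` rejects grades off the 0.5 grid;
the cohort loader accepts them with a warning, because field data sheets
contain averages of more than two examiners.

## Quality-control arithmetic

- **RSD** uses the sample (n−1) standard deviation: the convention for
  replicate precision at small n (the QC panels here have n = 7).
- **Percent difference** is symmetric, 100·|a−b|/((a+b)/2). Only this form
  reproduces the analyzer-vs-reference globulin cross-check (2.10 vs
  2.31 g/L → 9.5%); relative-to-either-argument forms give 9.1% or 10.0%.
- **Reference comparisons** report a *signed* difference relative to the
  reference center (measured minus center), plus a below/within/above call
  against the confidence interval.
- Values the analyzer reports at a detection-range bound are kept and
  flagged (`range_flags`), never censored; both range bounds are treated as
  inclusive.

## Univariate battery

Per variable: a dimorphism screen compares males vs females within each
health class; the variable is stratified by sex if either screen is
significant (this "either" rule is the conservative reading and matches
how three analytes and all three morphometrics end up stratified in study
data). Healthy-vs-diseased comparisons are then gated per group:
Shapiro–Wilk normality in *each* group and Levene (mean-centered) variance
homogeneity, all at α = 0.05, select between a classical equal-variance
two-tailed t-test and a two-sided Mann–Whitney U. The U test uses the
exact null distribution for small untied samples and the normal
approximation with tie and continuity corrections otherwise. Missing
values are removed pairwise per variable; a variable with an empty group
is skipped with a logged reason, never aborting the table. No
multiple-testing correction is applied by default (matching how such
panels are conventionally reported); α is a parameter throughout.

Calibration caveat: the screen-then-stratify procedure is adaptive, and on
signal-free data it inflates the per-row rejection rate from the nominal
0.05 to roughly 0.065–0.075 (measured on iid normal groups and on
generator nulls). This is a property of the procedure, not of the
implementation; the acceptance suite checks the rate stays within ±3
points of α.

## The network ensemble

**Architecture.** One hidden layer (default 5 logistic units), linear
output, prediction clipped to the target range ([0, 1] for binary status;
vet-score mode rescales 0–5 internally). Inputs are min-max scaled to
[0, 1] using each model's *training subset only*. Training minimizes
MSE + (λ/2)·‖W‖² by full-batch L-BFGS on analytic gradients; the loss at
every accepted iterate is recorded and is non-increasing. The only
randomness is weight initialization, so a seed fixes the model bitwise.

**Resampling.** 20 models, each trained on 70% of the complete-case
records (listwise exclusion over the *selected* features only — with CK in
the feature list exactly the one CK-less fish drops, n = 39 → 38). Draws
are stratified by class: each health class contributes 70% of its records.
Unstratified draws are available (`stratified=False`) but let each model's
training class balance leak into its held-out predictions; at n ≈ 38 that
induces a systematic anti-correlation between pooled cross-validation
predictions and labels, biasing null-data AUC far below 0.5. Stratification
removes the artifact; measured global-null AUC is 0.46–0.51.

**Metrics.** Fit R² and CV R² are squared Pearson correlations between
predicted and observed status on the training and held-out records of each
model, reported mean ± SD over the ensemble. Held-out predictions are
averaged per fish across the models that excluded it, and the ROC over
these pooled scores uses trapezoidal integration with ties contributing
half a concordance (so AUC equals the Mann–Whitney concordant-pair
statistic exactly); the reported AUC spread is the SD of per-model
held-out AUCs.

**Ridge default (λ = 0.02).** Chosen by a calibration study on synthetic
cohorts with planted effects: with λ ≤ 0.003 the 76-parameter network
interpolates its ~27 training points, and perturbation sensitivities rank
noise features as high as planted ones (top-4 recovery ≈ 0); with λ ≥ 0.03
the training fit degrades below what these panels typically report. λ =
0.02 balances a realistic fit/CV profile with a sensitivity ranking near
its information-theoretic ceiling (see *Limitations*). All hyperparameters
(hidden units, λ, iteration cap) are exposed in `AnnConfig`.

**Sensitivity.** For variable *j* and model *m*: shift *x<sub>j</sub>* by
+δ·range(*x<sub>j</sub>*) (δ = 0.05) for every record and average the
absolute change in predicted status; report mean ± SD over models. A
central-difference variant is available. Zero-range features are flagged
degenerate. Top-variable selection ranks analytes only (morphometrics are
not candidates), keeps the k = 4 best, always retains total length, and
re-admits age only when lethal sampling is acceptable; ties break by
larger mean then lexicographic code, deterministically, with a warning.

## Clamped surfaces

"Entire range" means the observed min–max of the modeling cohort (the
model is only trusted where data existed), clamp values are arithmetic
cohort means, and a 5% step gives 21 nodes per axis inclusive of both
endpoints. Each of the 20 models predicts the full 21×21 grid;
`mean_surface` and `sd_surface` are the across-model mean and SD (ddof=1).
`adequacy_summary` reports the fraction of nodes whose SD exceeds a
threshold and lists them as hotspots — near-zero SD regions need no
further sampling, high-SD regions do. Plot rendering is an optional thin
layer; the numeric grids (long-format CSV) are the contract.

## The synthetic cohort generator

The generator emulates the *statistical surface* of the study population:

- four sex-by-status groups of 9/10/9/11 fish;
- analytes drawn from a correlated multivariate normal with the printed
  group means and SD = SEM·√n; TP–ALB correlation ρ = 0.3 (protein
  analytes are mechanically linked through the derived globulin; no other
  covariance information is published), all else independent;
- GLOB computed per fish as TP − ALB exactly, never drawn;
- BA is unpublished at the group level (it was excluded from
  interpretation), so its defaults — mean 60, SD 20 µmol/L, inside the
  35–200 rotor range — are this package's realistic choice; BA feeds no
  downstream statistic;
- morphometrics drawn independently, ages rounded to whole years; per-sex
  length/weight means are chosen to satisfy every published anchor
  (healthy/diseased averages 39.4/42.4 cm, diseased males +10% and females
  +6% longer, males longer and heavier); morphometric SDs default to 10%
  of the mean (unpublished; a config knob);
- vet scores: healthy fish uniform over {0, 0.5}; diseased grades from a
  truncated geometric over {1, …, 5} (ratio 0.6) so low grades dominate —
  only the <1/≥1 split matters downstream;
- negative draws (and, under ALB ≥ TP, protein pairs) are redrawn;
  optional truncation to instrument ranges;
- `inject_study_artifacts` overlays the real missing-data topology:
  BA missing at rate 0.2, UA missing everywhere, exactly one fish without
  CK.

**What it does not emulate** — and hence what passing tests do *not* show
about real data: within-fish correlations beyond the TP/ALB link, skewed
or heavy-tailed analyte distributions, capture-stress effects, seasonal
structure, instrument censoring at range bounds, and lesion histology.
Gaussian cohorts are *cleaner* than real plasma panels: ensemble AUCs near
1.0 here correspond to the 0.85–0.92 range reported on real data, and the
near-perfect separation by age reflects the 10%-of-mean SD default rather
than field biology.

Because draws are positivity-truncated, group sample means for analytes
whose configured scale puts appreciable mass below zero (AST and CK in
some groups have SD ≳ mean) converge to the truncated-normal mean, which
sits above the configured value; convergence checks therefore cover the
cells with negligible truncation mass.

## Recovery and null experiments

`plant_effects` rewrites a config so that only named variables separate
the health classes (pooling the rest across statuses within sex) or, with
`null_shift=True`, equalizes all four groups — a clean global null.
Recovery experiments exclude GLOB from the network inputs: it equals
TP − ALB exactly, so it can neither be nulled independently nor compete
fairly with two planted variables whose signal it duplicates.

## Numerical choices

- L-BFGS with `ftol` 1e-10, `gtol` 1e-8, 400-iteration cap; exceeding the
  cap returns the model with a warning flag rather than failing.
- Weight init: N(0, 1/√fan-in) per layer, output bias at the target mean.
- Constant features scale to zero (denominator 1) instead of dividing by
  zero; constant targets are rejected.
- R² is defined as 0-information (NaN, excluded from aggregates) when
  either side of the correlation is constant or a held-out set has fewer
  than two records.
- Per-model seeds are `base_seed + model_index`, covering both the
  resampling draw and the initialization; every pipeline artifact embeds
  its replay config.

## Problem sizes used by the test and acceptance runs

The suites run the study-scale cohort (n = 39 → 38) throughout; rate
estimates use 100 seeded replicates for detection/recovery/null-AUC
checks, ≥500 variable-tests for type-I calibration, 200 random instances
for the AUC oracle, and five base seeds for ensemble performance
averages — sizes chosen so each estimate's Monte-Carlo error is small
relative to the band it is checked against.

## Known limitations

- **Sensitivity-ranking ceiling.** With the published effect sizes planted
  on Ca/Na/TP/ALB/length at n = 38, even an oracle that ranks variables by
  the exact two-sample t statistic recovers the top-4 chemistry set in
  only ~64% of replicates (top-5 in ~44%): the weaker planted effects
  (combined-sex d ≈ 0.8–1.0) sit near the noise floor of six competing
  null analytes. The ensemble's perturbation ranking reaches ~56% — most
  of that ceiling — so two acceptance checks that demand ≥80% recovery
  fail for information-theoretic reasons, not implementation ones.
- The adaptive univariate battery is mildly anti-conservative (see above).
- The ensemble is not a calibrated probability model; pooled predictions
  order fish well (AUC) but are not posterior disease probabilities.
- No multiple-testing correction by default; a survey re-using the battery
  across many sites should enable one.
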