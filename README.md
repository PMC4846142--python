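# steatnet

Non-lethal classification of pansteatitis — an inflammatory disease of
adipose tissue — from fish blood chemistry.

## The problem

Pansteatitis outbreaks in the Olifants River system (South Africa) have
killed crocodiles and fish at scale, but diagnosis normally requires
necropsy: veterinarians grade adipose lesions on a 0–5 scale, with a score
below 1 counting as healthy and ≥ 1 as diseased. Population-wide disease
surveys of living animals need a blood-based proxy. `steatnet` implements
the full analysis chain for evaluating a benchtop blood-chemistry panel
(12 analytes: AST, BA, CK, UA, GLU, PHOS, Ca²⁺, TP, ALB, GLOB, K⁺, Na⁺) as
such a proxy in Mozambique tilapia, for biologists and veterinary
epidemiologists running similar biomarker screens:

1. **QC arithmetic** — replicate precision as RSD = 100·s/x̄ (sample SD),
   symmetric percent difference 100·|a−b|/((a+b)/2), the analyzer's derived
   globulin GLOB = TP − ALB, and classification of measured means against
   certified reference intervals.
2. **Univariate battery** — for each analyte and morphometric trait
   (age, total length, weight): a sexual-dimorphism screen (male vs female
   within each health class), then healthy-vs-diseased comparisons per sex
   (if dimorphic) or combined (if not), each gated by Shapiro–Wilk and
   Levene checks onto a two-tailed t-test or a two-sided Mann–Whitney U.
3. **Network ensemble** — 20 feed-forward networks (one hidden layer of 5
   sigmoidal units, linear output clipped to [0, 1], ridge-penalized
   L-BFGS training), each fit to a random stratified 70% of the
   complete-case cohort with disease status coded 0/1. Per model: fit R²
   (squared Pearson correlation, training records) and CV R² (held-out
   records). Held-out predictions are pooled per fish into a ROC curve;
   AUC is the trapezoidal area (equal to the concordant-pair statistic).
4. **Sensitivity ranking and re-modeling** — per variable *j* and model,
   the mean absolute prediction change when *x<sub>j</sub>* shifts by +5%
   of its observed range; the four highest-ranked analytes plus total
   length form the non-lethal re-model (age is excluded: ageing a fish
   requires killing it for otoliths).
5. **Clamped surfaces** — all inputs but two clamped to cohort means, the
   pair swept over its observed range in 5% steps (21×21 grid); the
   ensemble mean maps the fitted response, the across-model SD maps
   sampling adequacy.
6. **Synthetic cohorts** — a generator that draws sex-by-status groups
   (9/10/9/11 fish) from correlated normals matching the study's printed
   group means ± SEM, derives GLOB per fish, assigns vet scores consistent
   with status, and reproduces the study's missing-data topology (BA
   sporadic, UA absent, one fish without CK). `plant_effects` builds
   parameter-recovery and global-null variants for calibration studies.

## Worked example

```bash
python examples/04_ensemble_roc.py
```

prints (seed 7 cohort, base seed 1):

```
full model on n=38 fish (excluded for missing features: ['SY0026']):
  fit R2 0.92 +/- 0.01   (squared correlation on each model's own training 70%)
  CV  R2 0.91 +/- 0.04   (same, on the held-out 30%)
  pooled CV AUC 1.00 +/- 0.00   (probability a diseased fish outscores a healthy one)
...
non-lethal re-model inputs: ['PHOS', 'ALB', 'TP', 'CK', 'total_length']
top-4 model: fit R2 0.69, pooled CV AUC 0.97 +/- 0.03
```

One fish is dropped because its CK value never registered (complete-case
rule over the selected features, so n = 38 of 39). Fit R² measures how well
each network reproduces its own training labels; CV R² and the pooled AUC
measure transfer to fish the model never saw — the quantity that matters
for a field diagnostic. The re-model shows that four analytes plus a ruler
retain most of the full panel's discrimination. Synthetic cohorts are
cleaner than real plasma chemistry, so these numbers sit above what a real
survey should expect; `docs/methods.md` discusses the gap.

Other entry points: `examples/01`–`05` cover QC, generation, the
comparison table and surfaces; the same stages are scriptable:

```bash
steatnet run --mode top4_nonlethal --seed 7 --out runs/demo
steatnet report runs/demo
```

Every run directory contains a `replay_config.yaml`; re-running from it
reproduces all numeric artifacts byte for byte.

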