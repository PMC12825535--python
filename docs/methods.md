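# Methods

`prediagprot` re-implements, as a tested reusable pipeline, a pre-diagnostic
plasma-proteomics analysis of a rare incident cancer in a biobank-style
prospective cohort: a proteome-wide Cox association scan over ~2,900 Olink
NPX variables, reconstruction and clustering of pre-diagnostic protein
trajectories from baseline-only measurements, a four-way causal mediation
decomposition of adiposity and smoking effects through plasma proteins, and
proteomic risk-model construction and evaluation. Because the motivating
cohort data are access-controlled, the package ships a first-class synthetic
cohort generator that emulates the data structure, and every statistical
guarantee is demonstrated against that generator's ground truth.

## Synthetic cohort generator

One row per participant with baseline covariates (age ~ U(40, 70), sex
Bernoulli(0.47), ethnicity 94% white, Townsend-like deprivation index
N(0, 3), ever-smoking Bernoulli(0.45), alcohol in three categories, BMI
N(27, 4.5) kg/m², hypertension 30%, diabetes 6%, creatinine N(72, 15)), and
a participants × proteins matrix of approximately standard-normal NPX
values.

**Event model.** Exponential proportional hazards: the log hazard is a sum
of planted per-SD protein effects, covariate effects, and (if configured)
the mediation terms below. Administrative censoring is drawn uniformly in
a ±1.3-year window around the configured median follow-up (default 11.76 y);
the baseline hazard is calibrated by bisection so the realized cumulative
incidence matches the configured rate (default 0.34%, ≈165 cases in a
48,851-participant cohort). This is the simplest generator consistent with
the proportional-hazards assumption the scan makes; it has no competing
risks and no informative censoring.

**Trajectory archetypes.** For cases only, each archetype protein's NPX gains
a deterministic z-scale offset `shape(lead time)` evaluated at the realized
years between blood draw and diagnosis:

1. early-abnormal exponential rise `3·exp(−t·ln3/15)` — z = 1.0 fifteen
   years out, z = 3 at diagnosis;
2. persistent elevation, constant z = 0.8;
3. logistic step centred 3 y pre-diagnosis (scale 0.8 y) rising 0 → 0.9;
4. Gaussian bump peaked 15 y out (height 0.9, SD 4 y), back to normal at
   diagnosis.

Magnitudes were chosen once so that the conventional z > 0.45 abnormality
threshold cleanly separates the regimes each shape is meant to represent
(always-abnormal, persistently elevated, late-onset, early-only); no
quantitative curve parameters exist to copy, so recovery tests assert
cluster separation and threshold-crossing behaviour, not exact curves.

**Mediation structure.** A continuous (standardized BMI) or binary
(ever-smoking) exposure A drives mediator proteins `M_p = β1_p·A + ε`,
ε ~ N(0, 1), and the log hazard gains `θ1·A + Σ_p (θ2·M_p + θ3·A·M_p)`.
The generator's ground-truth record carries the closed-form four-way
components at the reference contrast (a = 1 vs a* = 0, m* = 0); several
mediators sharing (θ2, θ3) aggregate exactly because a sum of independent
normals is normal.

**Missingness** is MCAR at a configurable per-cell rate (default 2%); the
mechanism of the motivating data is uncharacterized, so no MNAR structure
is attempted. What passing tests therefore show is correctness of the
estimators under MCAR, proportional hazards, normal mediators and
non-informative censoring — not robustness to violations of those
assumptions in real data.

## Preprocessing

Exclusion cascade (prior cancer first, then any missing covariate; counts
logged per step, a row failing both rules counts only once), a strict
">20% missing" protein filter (a protein missing in exactly 20% of rows is
retained), protein-wise k-nearest-neighbour imputation, and an unstratified
seeded 80/20 derivation/replication split with floor rounding
(48,851 → 39,080 + 9,771).

The imputation mirrors the gene-wise behaviour of the R `impute` package:
neighbours are proteins, the distance is the root-mean-square difference
over rows where both proteins are observed (pairs with no overlap are
unusable), and a missing cell is the average of the k nearest proteins'
values in that row, restricted to proteins observed there. A protein with
no usable peer falls back to its own observed mean, with a warning. A
brute-force oracle reproduces the implementation exactly on random matrices
up to 10×10.

## Proteome-wide Cox scan

One Cox model per protein: the protein (standardized to SD 1 within the
analysis set, so hazard ratios are per SD of NPX) plus the nine baseline
covariates. Ties use the Efron approximation. Bonferroni significance is
declared against a configurable family size (0.05/2911 = 1.7×10⁻⁵ for the
full panel) and BH-FDR q-values are computed over the tested family.
Failed fits are reported with NA statistics, never silently dropped.

The fits use an internal Newton–Raphson partial-likelihood solver with
suffix-sum risk sets, written because the calibration studies fit tens of
thousands of small models; its coefficients, standard errors and
log-likelihoods are asserted to match lifelines in the test suite.

Proportional hazards are checked per protein by correlating the protein
term's Schoenfeld residuals with the rank of the event times (exact t-test
on the Pearson correlation, flag at p < 0.01; indeterminate below three
events). Sensitivity variants: removing cases diagnosed within 2 years of
baseline (reverse causation; the multiplicity family stays at the full
panel size) and augmenting the covariate set (e.g. serum creatinine).

## Trajectory modelling

With a single baseline blood draw, the time from draw to diagnosis is the
progression axis: each case contributes one point at its own lead time and
the population of cases traces the trajectory. Stages:

- **Matching** — each case to 10 event-free controls, exact on sex, nearest
  on baseline age, without replacement, cases processed in a seeded random
  order, age ties broken by a seeded shuffle (no caliper: nearest-available).
- **Residualization** — per-protein OLS of NPX on the nine covariates fitted
  on controls only (so case signal is not absorbed), residuals applied to
  everyone.
- **Z-scores** — case value minus matched-control mean over matched-control
  SD (n−1 denominator), per case's own control set. Zero-SD cells become
  NaN with a warning.
- **LOESS** — degree-1 local linear regression with tricube weights,
  span 0.75, no robustness iterations, evaluated on a 0.25-year grid over
  [0, 15] years truncated to the observed lead-time range (no
  extrapolation). Degree 1 was chosen over R's default degree 2 for
  stability at the sparse edges of the lead-time range; it reproduces
  linear and constant inputs exactly, which the tests pin at 1e-8.
- **Abnormality calls** — all maximal grid intervals with z > 0.45 are
  recorded; the "sustained onset" is the start of the final exceedance run
  only if that run persists to diagnosis (lead time 0), making verbal
  statements like "abnormal from 15 years out" or "reverted to normal"
  computable. The threshold applies to LOESS predictions, not raw per-case
  z-scores.
- **Clustering** — pairwise Chebyshev (maximum) distance between curves,
  complete linkage, tree cut at k = 4; deterministic, with distance ties
  resolved by input order. A seeded 10-start k-means on the same prediction
  vectors serves as the stability sensitivity check.

## Four-way mediation decomposition

For exposure A, normal mediator M and a rare time-to-event outcome, the
mediator model `M = β0 + β1·A + β2'C + ε, ε ~ N(0, σ²)` (OLS) and the
outcome model `log h(t) = log h0(t) + θ1·A + θ2·M + θ3·A·M + θ4'C` (Cox)
yield, under the rare-outcome hazard-ratio ≈ risk-ratio approximation,
closed-form components on the excess-relative-risk scale via
`Q(a,a') = exp(θ1·a + (θ2+θ3·a)·μ(a') + ½(θ2+θ3·a)²σ²)`:
TE = CDE + INTref + INTmed + PIE exactly (the identity is grouped so the
β1 = 0 limit cancels in floating point, and holds to 1e-10 over random
parameter sweeps; each Q matches 80-node Gauss–Hermite integration to
1e-8 relative error).

A scientific point worth stating explicitly: because the decomposition is
additive on the ERR scale while the outcome model is log-linear, the two
interaction components do **not** vanish when the product term θ3 is zero —
at θ3 = 0 they collapse to
`INTmed = (e^{θ1Δa}−1)(e^{θ2β1Δa}−1)` and
`INTref = (e^{θ1Δa}−1)(1 − e^{θ2(m*−μ(a*)) − ½θ2²σ²})`.
Multiplicative no-interaction is not additive no-interaction. The β1 = 0
limit (no exposure→mediator path) does kill PIE and INTmed exactly.

Defaults exposed in `FourWaySpec`: index/reference contrast a = 1 vs
a* = 0 (one SD of BMI, or ever- vs never-smoking), m* = marginal sample
mean of the mediator, covariate level = design-column means. Uncertainty is
a seeded nonparametric percentile bootstrap (B = 500 by default, both
models refitted per resample; normal-approximation p-values from the
bootstrap SE), with a delta-method variant (numerical Jacobian against the
block-diagonal parameter covariance) for parity with the Stata
implementation of this estimator. Mediation is declared significant when
both TE and PIE have p < 0.05; the proportion mediated is PIE/TE, with
(PIE+INTmed)/TE also reported as "total mediated including interaction".

Candidate mediators are screened by requiring both legs significant at
0.05 (covariate-adjusted OLS exposure→protein, and the scan's Cox
protein→outcome p). For aggregation, mediators whose PIE and CDE point
estimates disagree in sign are excluded, the rest are standardized and
decomposed by PCA on the correlation matrix; components with eigenvalue
> 1 are retained (Kaiser; if none passes, the first component is kept with
a warning), scores standardized to SD 1. Each retained score is then run
through the same decomposition; with several components the combined
proportion sums component PIEs over the mean TE and is labelled an
approximation (the decomposition is nonlinear even for orthogonal scores).
Whether components should enter jointly or one at a time is genuinely open;
both the per-component results and the flagged combination are reported.
An optional filter can drop mediators with significant INTmed (off by
default).

## Risk models

- **Clinical** — bidirectional stepwise Cox from the full nine-covariate
  model, minimizing partial-likelihood AIC (−2ℓ + 2p); covariates move as
  whole dummy blocks. Deterministic given data.
- **Protein** — LASSO-penalized Cox (glmnet-style path via scikit-survival)
  over the BH-FDR hits, penalty chosen by k-fold (default 10)
  cross-validated partial-likelihood deviance in the Verweij–van
  Houwelingen form `−2[ℓ_all(β_fold) − ℓ_train(β_fold)]`; the
  nonzero-coefficient proteins are then refit unpenalized (selection, then
  use — the motivating analysis reports a discrete protein panel). An empty
  model at the deviance minimum steps down the path with a warning.
- **Combined** — stepwise AIC over the union of both models' features, with
  exact collinear duplicates dropped first.
- **Single marker** — univariate Cox on one standardized protein.

Models are frozen after fitting: evaluation computes linear predictors
only, never refits, enforcing derivation-fit / replication-evaluate
discipline. Metrics: Harrell's C with a seeded bootstrap percentile CI;
IPCW cumulative/dynamic time-dependent AUC on the integer horizon grid
2–10 years (horizons beyond follow-up or without events are reported as
missing, never 0 or 1); IDI at the 10-year horizon as the difference in
discrimination slopes of absolute 10-year risks (Breslow baseline), with
participants censored before the horizon excluded; a paired-bootstrap
p-value for the C-index difference against a reference model; and a
Youden-optimal cutoff on 10-year risk, intended to be computed on the
derivation split and applied unchanged to replication, with a log-rank
test for the dichotomized score.

## Orchestration

A YAML config drives simulate → preprocess → scan → trajectories → mediate
→ riskmodel. Per-stage seeds derive deterministically from one global seed
(CRC32 of "seed:stage", kept below 2³¹). Every output is delimited text or
JSON — no binary intermediates, so runs diff cleanly; a manifest records
stage parameters, seeds and SHA-256 digests, and reruns are byte-identical.
A failing stage halts the run with the stage named (exit code 3; config
validation errors exit 2), retaining earlier stages' outputs. The report
renderer assembles the scan, cluster, mediation and model-evaluation tables
into one markdown document, noting stages that did not run. Plots are
deliberately omitted in favour of tabular output.

## Problem sizes used in tests and the acceptance script

Calibration and recovery studies run at sizes chosen to make each check
statistically meaningful on a single CPU: family-wise error over 200 null
scans of 200 proteins at n = 2,000 with a 5% event rate; planted-effect
recovery and mediation coverage at n = 20,000 with the study-like 0.34%
incidence (~70 events) over 40 and 50 replicates (B = 200 bootstrap);
LASSO recall with 10 planted among 200 proteins at n = 10,000 with 1%
incidence; trajectory recovery from 24 curves of 120 cases each. The
synthetic defaults (48,851 participants, 2,911 proteins) remain the
generator's reference conditions.

## Known limitations

- The rare-outcome HR ≈ RR approximation degrades above ~5% cumulative
  incidence; `fit_models` warns rather than fails.
- The bootstrap refits both mediation models per resample; with very few
  events individual resamples can fail and are dropped (counted and
  logged).
- Matching is greedy without replacement; with a thin control pool late
  cases can receive fewer than 10 controls (logged).
- The Schoenfeld check is the correlation form only; it tests a monotone
  time trend in the effect, not arbitrary departures.
- k-means cluster labels are arbitrary up to permutation; agreement is
  always assessed via contingency/ARI, not raw labels.
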