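# Methods

`cfreferral` studies a question that recurs whenever a clinical prediction
model is moved between health systems: a risk model and referral policy are
developed on one cystic-fibrosis (CF) registry population (the *source*,
modelled on the 2014 UK adult CF cohort) and then applied unchanged to a
second population (the *target*, modelled on the 2014 Canadian adult CF
cohort) whose patients differ both in health status and in access to lung
transplantation (LTx). The package implements the whole chain — data model,
synthetic registry generator, calibrated risk ensemble, referral policies,
internal/external evaluation, per-feature transferability, and observed-risk
stratification — as reusable, tested code.

## Data model

A `PatientRecord` is one annual-review snapshot: demographics (age, sex,
height, weight, BMI), lung function (absolute FEV1 in litres and FEV1 %
predicted at the snapshot year and the three prior years), 12 treatment
flags, 2 treatment-day counts, 12 comorbidity flags, 4 microbiology flags, a
CFTR mutation-category pair from {A,B,C,D,O}², and three binary 3-year
outcomes: death, LTx, and their composite. The composite endpoint (death or
LTx within three years of the snapshot) is the prediction target throughout.

Selection is complete-case and adult-only (age ≥ 18 at the snapshot).
Because selection removes every incomplete record, the risk model never
imputes. Mutation pairs are stored in canonical alphabetical order ("BO",
never "OB"); the model input one-hot encodes them over the full 25-pair
grid, of which only the 15 canonical columns can ever be hot.

## Synthetic registry generator

Real UK/Canadian registry extracts are access-restricted, so the generator
is a first-class module that emulates the statistical structure the analysis
depends on. Per population it draws, for `n_patients` patients:

* **Flags** — independent Bernoulli draws at the published 2014 cohort
  incidences (e.g. hospitalization 46.14% UK vs 20.92% Canada, Pseudomonas
  71.69% vs 54.93%, home-IV antibiotics 36.94% vs 17.13%). Independence
  given FEV1% is a deliberate simplification: only marginals are published,
  not a joint distribution.
* **Lung function** — FEV1% three years before the snapshot from a normal
  distribution truncated to (10, 140], then three annual declines
  ~ N(2.0, 2.5²) % predicted/year, floored so FEV1% stays above 5. The
  preset start means are offset by three mean declines so the snapshot-year
  mean lands on the published values (69.10 UK, 66.24 Canada).
* **Continuous covariates** — age, height, weight, hospital days and
  home-IV days as log-normals matched to the published median and IQR
  (σ = ln(Q3/Q1)/(2·z₀.₇₅)); BMI computed exactly from height and weight;
  day counts only for patients with the corresponding flag.
* **Death** — one Bernoulli draw per patient with probability
  `logistic(β₀ + β·x + shift)`, where x = (FEV1%ₓ₀, oxygen therapy,
  hospitalized, home-IV, BMI) with β = (−0.07, +1.0, +0.7, +0.5, −0.06)
  log-odds per unit, and `shift` is an additive population-level offset
  (0 for the source, negative for the target — the target population's
  survival advantage at matched severity).
* **LTx** — among survivors with FEV1% ≤ 40 (eligibility ceiling), a
  Bernoulli draw at the population's access rate, optionally modified by
  per-flag log-odds offsets (`ltx_flag_logodds`, empty in the presets; it
  exists so experiments can make a flag drive transplant access without
  touching mortality). The composite outcome is death OR LTx; mortality is a
  fixed-horizon event, not time-to-event, because the endpoint is a 3-year
  binary.

The free outcome parameters — the mortality intercept, the target
population's shift, and both access rates — were fixed once by bisection
with the generator itself at n = 300,000 against the studied cohorts' event
rates: UK composite 6.66% (307/4,610) with 1.69% LTx uptake, Canada
composite 7.87% (158/2,008) with 4.33% uptake. The frozen values are
intercept 1.2654, shift −0.1045, access 0.1543 (UK) and 0.3485 (Canada).

`bayes_optimal_auc` scores a fresh simulated cohort with the exact
generative event probability (for the composite: P(death) + P(survive)·
P(LTx | survivor)) and returns its AUCROC — the ceiling any fitted model can
approach, used as the oracle in parameter-recovery tests. With the presets
this ceiling is ≈ 0.90.

**What the generator does not emulate:** flag–flag and flag–lung-function
correlation, height–weight correlation, longitudinal dynamics beyond four
FEV1% values, regional mutation spectra beyond the four published category
frequencies (remaining mass sits on "OO"), and any guideline-induced
feedback between referral practice and recorded treatment. Passing tests
therefore demonstrate that the analysis machinery recovers the structure
this generator encodes, not that the real registries behave this way.

## Risk model

Each member pipeline is scaler → dimensionality reducer → base classifier,
with Platt sigmoid calibration fitted on out-of-fold predictions and the
base model refit on the full training data (`ensemble=False`), so a member's
calibrated score is a monotone transform of its base score. Supported
components: {none, standard, min-max, uniform-quantile} scaling, {none,
variance-threshold, PCA(k), fast-ICA(k)} reduction, and {logistic
regression, random forest} base learners. The default candidate grid is the
three-pipeline flavour seen in practice: two regularized-logistic variants
and one random forest.

The ensemble is a convex combination of member probabilities. Search is a
bounded random search standing in for a full AutoML/Bayesian-optimization
framework: out-of-fold calibrated probabilities are computed once per
candidate (3-fold stratified CV on training data only), then up to
`search_budget` (default 10) weight vectors from a 0.1-step simplex grid are
scored by out-of-fold AUCROC, with every single-member vertex scored first —
so the selected ensemble never trails the best single pipeline on the
internal folds. Winning members are refit on the full training split.

## Referral policies

* `fev30`: refer iff FEV1 ≤ 30 % predicted.
* `guideline2019`: FEV1 < 30; or FEV1 < 50 with rapid decline in the past
  12 months (operationalized: year-over-year drop ≥ 10 points); or FEV1 < 40
  with ≥ 1 marker of reduced survival (default set: oxygen therapy,
  hospitalization > 28 days, *B. cepacia*, BMI < 18.5, hemoptysis,
  pneumothorax; configurable by name). The published criteria do not fix
  either operationalization, so both are explicit, documented parameters.
* `ml`: refer iff ensemble score ≥ threshold, the threshold chosen to
  maximize F1 over the observed training scores (exhaustive; ties break to
  the largest threshold, i.e. fewest referrals). Score-at-threshold refers.
* `augmented`: `ml` plus two rescue criteria — FEV1 ≤ 30, or FEV1 ≤ 40 with
  an absolute 3-year decline ΔFEV1 ≥ 10 points — targeting the target-
  population subgroups where a transported model under-refers. By
  construction its referral set is a superset of `ml`'s.

## Evaluation design

Endpoint-stratified 10-fold cross-validation on the source cohort. Per fold
the ensemble and its threshold are fitted on the training split only;
policies are then evaluated on (i) the held-out source fold (*internal*),
(ii) the entire target cohort (*external*), and (iii) the full source cohort
(*source_full*, the view used for source-population timeliness counts,
which include training patients by design). Metrics are PPV, TPR, F1
(per-fold values averaged, not harmonic mean of averages), AUCROC/AUCPRC for
the score-based policy, and timeliness: among patients with the adverse
outcome, *timely* = referred at the snapshot, *delayed* = missed;
delayed + timely always equals the adverse count and timely/adverse equals
TPR exactly. Fold spread is reported as a 95% CI halfwidth under a normal
approximation, 1.96·sd/√k (the formula is a package choice; swap-in of a
t-quantile is a one-line change). Rule-based policies make identical
external predictions every fold, so their external halfwidths are exactly 0.
Metrics with empty denominators return 0 with a warning.

## Transferability

For each feature, a univariate logistic model is refitted per source fold;
its held-out source AUCROC and full-target AUCROC are averaged over folds.
A univariate monotone model's AUC equals the feature's own rank-AUC, which
the tests exploit as an oracle. A feature is *predictive* if either AUC
reaches 0.6; predictive features keep the *shared* label while the target
AUC is within 0.02 of the source AUC (the margin makes the visual notion
"close to the diagonal" explicit), else *degraded*. Both the composite and
the death-only endpoint are analysed; death-only retains LTx recipients as
non-events by default (an `endpoint` flag can exclude them instead), which
separates mortality shift from transplant-access shift.

## Risk stratification and mismatch

Strata are defined on the observed-risk scale: low/moderate/high collect
patients whose observed adverse-outcome rate lies in [0, 0.1), [0.1, 0.5),
[0.5, 1.0]. Cutoff search: sort patients by score, smooth the 0/1 outcome
sequence with a centered moving average, enforce monotonicity by isotonic
regression, and read off where the adjusted risk first reaches 0.1 and 0.5,
taking the middle observed score of the isotonic plateau that straddles each
level (less biased than the plateau edge, and — being an observed score —
equivariant under monotone transforms of the score axis). The default
neighbourhood is scale-aware: 5% of the cohort, floored at 201 patients and
capped at a quarter of the cohort. A fixed small window cannot tighten with
n (the estimator's sd at risk level p is ≈ √(p(1−p)/window)), and the
scale-aware default recovers the 0.1/0.5 cutoffs within 0.02 on perfectly
calibrated scores at n = 20,000. Boundary scores assign upward, so the
high stratum is closed on the left. If the adjusted risk never reaches a
level the cutoff is 1 and the stratum is empty (warned).

The mismatch analysis fits one model per population, derives each
population's strata, and cross-tabulates the two stratum labels on the
target cohort: agreement is the diagonal fraction; *mismatch 1* (source
low, target moderate) and *mismatch 2* (source moderate, target high) are
the under-call cells, reported with per-cell observed adverse rates and
subgroup descriptors (share with FEV1 ≤ 30, share with FEV1 ≤ 40 and
ΔFEV1 ≥ 10, oxygen-therapy rate, median FEV1%).

## Problem sizes and determinism

The packaged study runs the source at n = 5,000 and the target at n = 2,000
with k = 10 folds and search budget 10 — large enough for the
cross-population contrasts to be stable, small enough for a single CPU to
complete the full pipeline in a few minutes. Calibration-suite tests use
n = 10,000 (marginals) and n = 20,000 (cutoff recovery). All stochastic
stages take explicit seeds; reruns with the same configuration are
bit-identical.

## Known limitations

* Marginal-only emulation means interaction-driven phenomena (e.g. a model
  exploiting flag correlations) are out of reach of the test bed.
* The bounded random search is a stand-in for full AutoML; it will not find
  exotic pipeline combinations, and neural-network/XGBoost learners are not
  in the default grid.
* The published headline numbers that depend on the real registries
  (internal AUCROC 0.91 / external 0.88 as point contrasts, specific
  PPV/TPR cells, the 86.3% agreement and 22.9%/68.0% mismatch-cell risks)
  are not reproduction targets; the package reproduces the *qualitative*
  pattern — external TPR of the transported score drops sharply while the
  augmented policy restores F1 above the original — under its own synthetic
  study conditions.
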