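# Methods

`bioagestack` implements a complete biological-age (BA) analysis pipeline on
synthetic physical-examination cohorts: missing-value imputation
benchmarking, two-step feature screening, a stacked-ensemble BA estimator
contrasted with deliberately overfit boosted-tree BAs, and association
batteries linking BA to body-shape indices and disease status. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## Synthetic cohort generator

Real examination cohorts of this kind are not publicly distributable, so all
experiments run on a seeded generator that reproduces the statistical
structure the downstream analysis relies on, not any real population's joint
distribution.

Each participant has chronological age CA ~ Uniform(45, 90) years and a
latent per-person aging offset δ ~ N(0, 5) years (females shifted −1 year,
mirroring the common finding that women are biologically younger at a given
CA). The *effective age* EA = CA + δ drives the biomarkers:

* **Continuous markers** (13 biochemical panels, in conventional units,
  e.g. SBP in mmHg with +0.45 mmHg/yr): conditional mean
  `base_mean + age_slope·(EA − 65) + gender_shift·female (+ quadratic)`,
  Gaussian noise partially shared within correlation blocks (blood pressure,
  blood counts, liver enzymes, lipids; within-block noise correlation 0.35).
* **Binary urine markers**: logistic in EA. Urine protein carries an age
  slope; urine sugar, ketone and occult blood are generated with *no* age
  signal — they exist to be screened out by feature selection.
* **Anthropometry**: height shrinks mildly with EA; weight derives from a
  latent BMI; waist carries an explicit δ loading (0.004 m per year of δ),
  which plants the aging-rate signal into ABSI and WHtR. BMI is stored as
  weight/height² exactly.
* **Gender** is age-dependent (log-odds of female +0.018 per year around the
  age midpoint): in a 45–90 cohort the fraction female rises with age
  because women outlive men, and this is also what makes gender a
  legitimately age-correlated candidate feature.
* **Diseases** (7 flags): Bernoulli with logit linear in (CA − 65), δ and a
  binary family-history covariate, so faster agers are sicker at fixed CA.
* An optional **calibration count** is drawn Poisson with log-rate linear in
  (CA − 65) and δ. It exists because a sum of seven Bernoulli flags is
  Poisson-binomial — there is no exact "planted Poisson coefficient" to
  recover — whereas this column gives the Poisson battery an exactly
  specified truth for CI-coverage checks.

`latent_delta` is written to the table as an oracle-only column; every
estimation stage calls `assert_no_oracle` and refuses tables that still
contain it.

What the generator does **not** emulate: real marker distributions (skewness,
detection limits, measurement rounding), longitudinal records, mortality
outcomes, and informative missingness coupled across variables. Passing
tests therefore demonstrate that the pipeline's logic behaves as designed
under a known truth — not that any particular imputer or BA model is best on
real examination data.

## Missingness injection

* **MCAR** removes `round_half_up(rate · cells)` cells from the 19-column
  maskable block (13 continuous markers, 4 urine binaries, height, weight;
  age, gender, disease flags and derived columns are never masked). Cells
  are taken as a prefix of a seeded permutation, so masks at increasing
  rates nest under a fixed seed — rate comparisons then share their masked
  cells (common random numbers), which is what makes the benchmark's
  rate-monotonicity comparisons resolvable at desk scale.
* **MNAR** removes `round_half_up(rate · n)` values per listed column, with
  selection weights `softmax(strength · standardized value rank)`. The
  default strength 0.5 is a mild upper-tail bias: higher values are more
  likely to go missing, making the mechanism genuinely not-at-random while
  the realized per-column counts still match the requested rates exactly.
  The default profile covers the columns with a >2% observed missing ratio
  and averages ≈5% overall.

## Imputers

All five methods operate on the standardized scale defined by training-row
means/variances, de-standardize afterwards, never touch observed cells, and
threshold binary fills at 0.5 (strictly greater maps to 1).

* **mean** — training column mean.
* **knn** (k = 10 default, grid-searchable) — sklearn `KNNImputer`,
  NaN-aware Euclidean distance over jointly observed coordinates.
* **round_robin_regression** — sklearn `IterativeImputer` cycling columns in
  ascending-missingness order, max 10 cycles, tolerance 1e-3. The per-column
  linear model is a ridge regression with penalty 0.05 × (fit rows). The
  penalty is a numerical-stability choice, not a tuning knob: with an
  unpenalized linear model the chained fixed-point iteration can acquire a
  spectral radius above one when coefficients are estimated from
  weakly-correlated, partially-imputed data, and at a 30% missing rate the
  iteration then drifts to a solution worse than the column mean. The 5%
  ridge damps that feedback at negligible cost to low-rate accuracy.
* **chained_multiple** (m = 5) — the same cycling with stochastic draws
  (`sample_posterior` Bayesian ridge); continuous cells are averaged over
  the m completions, binary cells majority-voted after thresholding.
* **autoencoder** — a numpy feed-forward encoder–decoder
  (19 → 12 → 6 → 12 → 19, tanh hidden layers, linear output) trained with
  Adam (lr 1e-3, batch 64, 200 epochs). Training is denoising-style: each
  batch hides a further 30% of the observed inputs and the squared loss is
  taken over exactly those hidden cells, so the training objective is the
  imputation task itself. The corruption rate matches the top of the
  benchmark's missing-rate grid, which is what keeps the reconstruction
  accuracy flat as the inference-time missing rate grows; with a plain
  reconstruction loss the network leans on an identity component that
  degrades as inputs are zeroed.

## Benchmark protocol

For each (mechanism, rate, method): split rows 80/20, compute
standardization statistics on the complete training rows, inject missingness
into the full block, fit the imputer on the training partition, impute
everything, and score masked cells of the test partition — standardized MSE,
and R² as the coefficient of determination about the masked-cell truth mean
(so biased imputations are penalized; squared correlation would not do
that). The test rows are divided into ten folds scored separately, giving
mean ± SD fold replicates. An optional per-method parameter grid is tuned on
the training partition's masked cells only. Wall-clock time is recorded but
hardware-bound, so it is never an acceptance quantity.

Because masked-cell difficulty varies between injections, cross-rate
comparisons of raw MSE are noisy even with nested masks; degradation-in-rate
statements are therefore made on the mask-difficulty-normalized scale
(method MSE relative to the mean-imputer MSE on the same mask, or
equivalently R²).

## Feature selection

Standardized candidates (22: 13 continuous markers, 4 urine binaries,
gender, height, weight, waist, BMI) are screened by cross-validated lasso
against CA (minimum-CV-error penalty, 10 folds), then by a two-tailed
Pearson test against CA at α = 0.05 (binary features reduce to the
point-biserial form, the identical statistic). A feature is kept iff its
lasso coefficient is nonzero and its correlation is significant. Constant
columns are flagged as degenerate rather than silently dropped.

Two facts about this screen are inherent and worth stating: a feature with
no age signal still clears the Pearson gate with probability α, and the
functionally dependent trio height/weight/BMI gives the lasso a free choice
near the CV-minimum penalty. The screen's *count* of kept features is
therefore a stochastic quantity; the deterministic 22 − 3 = 19 bookkeeping
is exposed separately (`selection_accounting`).

## BA models

**Stacked estimator** (`StackedBioAge`): 80/20 split; each of five base
models (XGBoost, LightGBM, classic gradient boosting, histogram gradient
boosting, extremely randomized trees — family slots with modest ensemble
sizes so a full ten-fold run stays interactive on one core) runs ten-fold CV
inside the training partition. The concatenated out-of-fold predictions form
the level-2 training features; the mean of the ten fold-models' predictions
on the test partition forms the level-2 test features. A deliberately simple
meta-model — an additive B-spline regression (statsmodels GLMGam, 6 df per
base model, evaluation clipped to the training range), with linear, SVR and
random-forest alternatives available — is fitted on the level-2 training
features with CA as the response. Full-sample BA applies the meta-model to
the level-2 features, i.e. training rows keep their out-of-fold values.
The alternative (refitting each base on the whole training set for
full-sample prediction) would reintroduce exactly the leakage the contrast
model demonstrates, so the out-of-fold convention is pinned. A
fold-membership audit (`audit_no_leakage`) verifies from recorded provenance
that no training row was predicted by a fold-model that trained on it.
The random-forest meta-model is available but warned against in the API
docs, since a flexible meta-learner reintroduces the train/test gap.

**Boosted contrast** (`BoostedBioAge`): a single XGBoost model trained on
the training partition and applied to the full sample — the leakage pattern
under study, reproduced deliberately. `moderate` inherits the stacked
ensemble's boosted-tree settings. `overfit` searches a fixed 11-point grid
(configurations adjacent to the moderate model first, then deeper/longer
ones) for the candidate maximizing training-set Pearson r subject to the
test MAE staying approximately unchanged. "Approximately unchanged" is
`max(1%, 2 paired standard errors)` of the relative test-MAE difference: the
tolerance scales with the test partition's sampling noise, tightening to the
1% floor at very large n while not demanding a distinction a 600-row test
set cannot measure. An empty admissible set raises with the full search log
attached.

Pearson correlations carry Fisher-z 95% CIs. Feature-importance values are
taken per base model (tree gain; |standardized coefficient| for linear
models; permutation importance otherwise), normalized to sum to one within
each model, and averaged.

## Association batteries

ABSI = WC / (BMI^(2/3) · Height^(1/2)) with waist and height in metres;
WHtR = waist/height. Three batteries, each as a crude Model 1 and an
adjusted Model 2:

1. **Risk indicators**: OLS of BA on the continuous index, plus a quintile
   version (empirical quintiles, ties broken by stable participant order so
   group sizes differ by at most one) reporting per-quintile BA increments
   against Q1. Model 2 adjusts for CA, BMI, family disease.
2. **Disease counts**: OLS of BA on the 0 / 1 / 2+ count category (BA
   increments), and Poisson regression of the raw 0–7 count on BA with CA
   as a covariate, not an offset. Model 2 adjusts for CA, family disease.
3. **Specific diseases**: one logistic regression per flag; OR per year of
   BA with Wald 95% CIs on the log-odds scale. Perfect separation is
   reported as a diagnostic on the result row rather than raised.

P-values are two-tailed throughout, and no multiplicity correction is
applied — a deliberate mirror of common practice in this literature, noted
rather than fixed. Estimation is maximum likelihood via statsmodels; the
test suite checks the linear/Poisson/logistic estimates against an
independent numpy IRLS implementation to 1e-8 on a 30-row fixture.

## Problem sizes and numerical choices

The test and acceptance runs use sizes chosen to keep the full suite
interactive on a single core while leaving the compared effects well above
their Monte-Carlo noise: imputation benchmark on 5,000 rows (tenfold
scoring, MCAR 5–30%), stacked-vs-overfit contrast on ten 3,000-row cohorts,
CI-coverage calibration on 200 cohorts of 2,000 rows. Rounding of removal
counts is round-half-up, making counts exactly testable. Quintile ties break
by stable input order. Degenerate cases (constant response, constant
feature, empty mask, all-missing column, zero reference range) raise or are
flagged explicitly rather than propagating NaNs.

## Known limitations

* The generator's markers are conditionally Gaussian with linear age
  trends; heavy tails, floor/ceiling effects and measurement rounding are
  absent, which flatters regression-based imputation.
* Stacked/overfit orderings are demonstrated as orderings on synthetic
  cohorts; the magnitudes (gap ratios, z statistics) are functions of the
  generator's planted effect sizes and scale with n.
* The overfit search treats "test MAE approximately unchanged" statistically;
  on very small test partitions the admissible set can still be empty, which
  is reported with the search log rather than silently relaxed.
* Survival analysis, external validation cohorts, and convolutional
  architectures for tabular data are out of scope.
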