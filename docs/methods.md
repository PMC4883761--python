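# Methods

This note documents the statistical procedures implemented in `postoprisk`,
the design of the synthetic-cohort generator, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The prediction problem

Two binary postoperative outcomes are modelled from preoperative data: an
AKI-like outcome with ~36% prevalence and a severe-sepsis-like outcome with
~5% prevalence. All models act on the logit scale,

    logit P(E = 1 | X = x) = α + Σᵢ fᵢ(xᵢ),

with the per-feature contribution fᵢ linear (logistic regression), a cubic
spline (GAM), an implied per-feature log-likelihood-ratio (naive Bayes), or
absorbed into a kernelized margin (SVM).

## Preprocessing

**Outlier rule.** A continuous observation is an outlier when it lies
strictly below the 1st or strictly above the 99th empirical percentile of
its feature (linear-interpolation quantiles; the quantile estimator is a
package choice — the rule itself only fixes the 1% tails). Outliers are
removed and then treated as missing; all missing continuous entries are
imputed with the mean of the retained values; missing nominal entries
become a reserved `__missing__` level that downstream encoders treat as an
ordinary level. Cleaning statistics follow the fit/transform idiom so they
can be estimated on a training fold and applied to validation. Repeated
cleaning is exactly idempotent when quantile re-flagging is disabled on the
second pass; with re-flagging, a second pass would re-trim up to 2% around
the imputed mean, which is why the flag exists.

**Outcome-conditional encoding.** A nominal level x is scored by
log[P(X=x|E=1)/P(X=x|E=0)] with conditional probabilities estimated from
level counts. A symmetric pseudo-count (default 0.5, added to both cells
and twice to both class totals) guards zero cells; the raw ratio is the
smoothing → 0 limit. For a binary outcome the raw score is strictly
monotone in the level's event rate, which is exactly the condition under
which the optimal binary split by Gini impurity or cross-entropy is
achievable as a threshold on the encoded value; the test suite verifies
this against brute-force enumeration of all level partitions. Levels with
fewer than 100 records (strict, "fewer than") are pooled and the pool is
subdivided by 1-D k-means on the per-level event proportion — one-
dimensional because, for a binary outcome, "similar class proportions" is a
scalar property. The effective cluster count is min(5, number of distinct
proportions); 10 k-means restarts with a fixed seed make it deterministic,
and subgroup ids are relabelled by ascending cluster centre. Levels unseen
at transform time receive the score of the largest pooled subgroup — the
most populous low-count stratum is the natural prior for a level we know
nothing about; if nothing was pooled, the fallback is 0 (the marginal
score).

**Procedure-code aggregation.** Codes are digit strings of length 2–4
(a decimal point, as in `81.54`, is stripped on read); the digit prefixes
define nested procedure classes. A prefix tree stores, per node, the
patients coded exactly at that node and in its subtree. Aggregation runs
bottom-up with siblings processed in lexicographic order: a code with at
least `min_count` patients keeps its own group; under-threshold siblings
merge into a residual group at their parent prefix; residuals still under
threshold merge upward again; residuals reaching the 2-digit top level are
retained regardless of size (a flag pools them globally instead). The
2-digit level is treated as the top of the hierarchy generically — the
number of top classes is whatever the data contain, not a hard-coded
constant. The threshold is chosen from {50, 100, 150, 250, 500} by a
grid search whose criterion — held-out univariate AUC of a logistic model
on the encoded grouping — is a package choice; ties go to the smaller
candidate. Unseen codes at transform time route to the deepest existing
ancestor group, then to their top-class residual, then to a global
`__other__`.

## Models

**Logistic regression** is fitted by IRLS (unpenalized maximum
likelihood); perfect separation falls back to a lightly ridge-penalized fit
with a warning.

**GAM.** Designated continuous features get cubic B-spline bases (10
degrees of freedom per term, degree 3); everything else enters linearly.
Per-term smoothing penalties are selected by minimizing AICc
(deviance + 2·edf + small-sample correction) over a decade grid
10⁻²…10⁷ — first a single shared weight, then (`search="refine"`)
coordinate-wise refinement per term. Penalized-likelihood selection by AICc
is used in place of restricted-likelihood maximization, which the
underlying GLM-GAM machinery does not expose; for the purpose served here
(deciding how much curvature each term keeps) the two criteria are
interchangeable in practice. After fitting, terms with effective degrees of
freedom below 1.5 ("close to 1"; the cutoff is a package choice since
"close" is not quantified) are demoted and the model is refit with those
terms linear — yielding the explicit partition into linear weights and
smooth functions. A smoothed candidate with fewer than 10 distinct values
is demoted up front. Predictions clamp new data to the training knot span
(constant extrapolation). With no smooth terms the GAM is exactly the
logistic model, and the test suite asserts risk agreement to 1e-6.

The repeated-split harness uses the shared-weight search by default; the
coordinate-wise refinement is reserved for the focused recovery analyses.
This is a compute/precision trade-off: refinement changes per-term edf
allocation but moves validation AUC by well under a bootstrap CI width.

**Naive Bayes.** Class priors from outcome frequencies; continuous
conditionals Gaussian per class with variances floored at 1e-9; binary and
log-ratio-encoded categorical features use per-class frequency tables with
Laplace pseudo-count 1 (keyed by the encoded value, which is constant
within a group). The posterior is normalized over both classes. Note that
a frequency table on an encoded feature contributes approximately the
encoded log-ratio itself with weight 1 — on data whose true risk is
additive with independent features this makes naive Bayes nearly
well-specified, a point that matters for model comparisons (below).

**SVM.** Soft-margin SVM on internally standardized features; default RBF
kernel with the median-pairwise-distance heuristic bandwidth (1/(2·med²),
median over ≤1000 subsampled rows), cost C = 1, and inverse-prevalence
class weights so the 5%-prevalence outcome is not ignored. The kernel,
cost and weighting are package choices — no reference values exist for
them. Decision scores w·x − b are used directly for AUC and thresholded at
0 for accuracy/PPV; an optional Platt flag exposes calibrated
probabilities, without which calibration statistics are not computed for
the SVM.

All models serialize to JSON-ready dictionaries (coefficients, spline
knots and weights, NB tables, SVM support vectors) sufficient for exact
re-scoring.

## Reduction arms

Univariate screening keeps features whose single-covariate logistic Wald
p-value is below 0.2 (constant features are excluded with a warning).
LASSO selection standardizes internally and picks the penalty by 5-fold
cross-validated deviance; the selected set is the nonzero support. PCA
standardizes to the correlation scale (obligatory with mixed-unit clinical
features; covariance-scale PCA would be dominated by whichever lab has the
largest variance) and keeps the top 5 components. All three are fitted on
the training fold only in honest mode. Very rare binary indicators
(< 2% prevalence) can be replaced by a summed composite index.

## Evaluation

Repeated stratified 70/30 splits (per-class allocation, so prevalence is
preserved to rounding in both partitions), default 50 repetitions. AUC is
the Mann-Whitney statistic with ties counted half, asserted equal to
exhaustive pair enumeration to 1e-12. Accuracy and PPV use a probability
threshold of 0.5 (0 for SVM decision scores); PPV is reported missing when
no patient is predicted positive. Confidence intervals are computed two
ways and labelled: a percentile bootstrap (B = 2000) over validation
patients within a split, and the 2.5/97.5 percentiles of the metric across
repetitions — the first measures sampling noise of one validation set, the
second split-to-split variability. Hosmer-Lemeshow uses 10 equal-size
risk-ordered groups, χ² = Σ (O−E)²/(n·p̄(1−p̄)) against χ² with g−2 degrees
of freedom (the classic null for an in-sample fitted model); groups with
degenerate expected counts merge into their neighbour. Paired model
comparison uses the two-sided Wilcoxon signed-rank test over per-repetition
AUCs ("nonparametric" is otherwise unspecified; all-zero differences give
p = 1).

### Preprocessing leakage: honest mode vs whole-cohort mode

Target encoding fitted on data that includes the validation fold leaks
outcome information into validation scores. The harness therefore defaults
to fitting every transform on the training fold (honest mode) and offers
`paper_mode=True` for whole-cohort preprocessing before splitting — the
design under which headline performance tables of this kind are typically
produced. The two modes answer different questions and can reverse model
rankings: with fold-wise encoding, the encoded high-cardinality features
carry training-specific noise; a jointly-fitted logistic model shifts
weight onto the leakiest encoded feature and away from correlated honest
ones, while naive Bayes' per-feature weight-1 contributions are unaffected
— at the cohort sizes used here this lets naive Bayes overtake logistic
regression, most visibly for the rare outcome. Under whole-cohort
preprocessing the encoded features behave consistently across folds and
the discriminative models (GAM, logistic) dominate naive Bayes, the
ordering the acceptance suite asserts. The test suite separately asserts
the leakage direction itself: paper-mode AUC ≥ honest-mode AUC per
repetition on a high-cardinality cohort.

## The synthetic-cohort generator

The generator emulates the schema and statistical structure of a
perioperative EHR cohort; its defaults are the package's study conditions.

- **Continuous labs/demographics** (units: years, mg/dl, ml/min/1.73m²,
  %, g/dl): age ~ N(56, 16²); reference creatinine log-normal
  (median ≈ 0.85 mg/dl); eGFR ~ N(90, 25²) with latent correlation −0.85
  to creatinine (eGFR is computed from creatinine in practice);
  hematocrit ~ N(34.3, 6²); hemoglobin ~ N(11.7, 2.2²) with latent
  correlation 0.9 to hematocrit.
- **True continuous effects**, on the standardized scale: age linear
  (β = 0.35); hematocrit U-shaped f(z) = 0.12(z²−1) − 0.25z; hemoglobin
  weakly U-shaped (a = 0.05); eGFR a = 0.05, b = −0.35. The curvature is
  deliberately mild: strong U-shapes would hand naive Bayes (whose
  class-conditional variances capture quadratic risk) an advantage over
  logistic regression that contradicts the regime this class of cohort
  exhibits, where GAM improves on logistic by far less than both improve
  on naive Bayes. Amplitudes are configurable for studies of stronger
  nonlinearity, and the recovery analyses use a = 1 U-shapes.
- **Ten binary comorbidity/medication indicators** with realistic rates
  (diabetes 0.17, CHF 0.08, …), most coupled to age through a
  latent-normal copula (loadings 0.3–0.5) so comorbidities co-occur and
  track age as they do in real cohorts; effects drawn N(0.25, 0.2²).
- **High-cardinality nominal features**: a surgeon identifier with 500
  levels and an area code with 70 levels, Zipf-distributed level
  frequencies (exponents 1.15 / 1.1), i.i.d. normal level effects
  (sd 0.35 / 0.20). Surgeons are linked to procedure classes (each surgeon
  operates within one top class) — surgeons specialize, so surgeon
  identity co-varies with procedure and case mix.
- **Hierarchical procedure codes**: 18 two-digit top classes × 5 × 6
  leaves; Zipf leaf frequencies within class; per-patient top-class
  probabilities tilted by age (per-class loadings ~ N(0, 0.6)); true
  effects drawn independently at depths 2/3/4 (sd 0.25/0.15/0.10) so risk
  signal exists at every granularity.
- **Outcomes** are drawn Bernoulli from the additive logit model after the
  intercept is calibrated by bracketed root finding so the expected
  prevalence equals the target to 1e-4. The two outcomes are independent
  given covariates.
- **Corruption**: missingness is MCAR (the simplest mechanism consistent
  with mean imputation); injected outliers are placed beyond ±magnitude
  scale units from the feature mean with recorded indices, providing the
  oracle for detection tests.
- One master seed; every stage draws from its own deterministically
  spawned child stream, so identical (spec, seed) give bitwise-identical
  cohorts.

**What passing tests do and do not show.** The generator produces additive
logit-scale risk with Gaussian/latent-Gaussian dependence, MCAR
missingness, and independent outcomes. Real EHR data have informative
missingness, interactions, temporal structure, label noise from outcome
adjudication, and AKI–sepsis dependence — none of which are modelled.
Tests passing here certify the pipeline's mechanics and its statistical
operating characteristics under the stated conditions, not clinical
performance.

## Problem sizes

Recovery and model-ordering analyses run at n = 20,000 patients (single
cohort for recovery; 20 seeds for the ordering property). Operating-
characteristic simulations use 200 replicates (univariate screen at
n = 10,000; calibration at n = 2,000; bootstrap coverage at n = 1,000 with
B = 1,000). The acceptance script reproduces the full factorial experiment
at n = 6,000 with 5 repetitions and an SVM training cap of 3,500 rows —
sizes chosen so a complete reproduction runs in about a minute on one CPU
while keeping every Monte-Carlo band comfortably wider than its sampling
noise.

## Known limitations

- REML-based smoothing selection is approximated by AICc grid search
  (see GAM section).
- The SVM is uncalibrated by default; its accuracy/PPV at threshold 0 are
  not comparable to the probabilistic models' at 0.5.
- The sepsis outcome at desk scale (n ≈ 20,000, ~1,000 events) is far
  noisier than in a full-size registry; encoded high-cardinality features
  are mostly leakage noise for it in honest mode.
- Whole-cohort mode reproduces an optimistic design faithfully; its
  absolute AUCs should not be read as honest estimates.
- The sample-size calculation for a target CI width is not implemented:
  the stated reference calculation is not reproducible without the assumed
  AUC and CI formula.
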