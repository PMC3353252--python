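# Methods

## Problem setting

`riskport` transports published logistic risk-prediction models for incident
type 2 diabetes (the San Antonio Heart Study, Atherosclerosis Risk in
Communities, and Framingham Offspring functions) into a new multi-ethnic
population, refits local counterparts, recalibrates the external models, and
measures discrimination and calibration. The setting it emulates is a 1990s
Singapore health-survey cohort of Chinese, Malay and Indian adults followed
for incident diabetes over roughly a decade, with about 7.8% cumulative
incidence.

A risk model is an ordered list of covariate encodings (term specs) plus a
coefficient vector `beta` and, when known, an intercept. Subjects carry SI
units (glucose and lipids in mmol/L); the American models score glucose and
lipids in mg/dl, so encodings perform the molar-mass conversions (glucose
18.0182, cholesterol 38.67, triglyceride 88.57 mg/dl per mmol/L). Absolute
risk is `p = 1/(1 + exp(-y))` with `y = b0 + x'beta`.

The published coefficient vectors ship with the package; the original
publications' intercepts do not, so `RiskModel.intercept` is `None` for
published models and every absolute-risk use of them goes through
recalibration (which needs no external intercept) or a user-supplied
constant. This is deliberate: fabricating an intercept would silently decide
the baseline risk.

### Eligibility and outcome

Subjects with physician-diagnosed diabetes, baseline fasting glucose
>= 7.0 mmol/L, or 2-hour post-challenge glucose >= 11.1 mmol/L are excluded
at baseline (all clinical thresholds inclusive). Incident diabetes at
follow-up is a follow-up fasting glucose >= 7.0 mmol/L or a physician
diagnosis; a subject with neither measurement has an unknown outcome and is
routed to the imputation module.

### Framingham dichotomizations

The Framingham function uses binary risk factors whose exact cutoffs are a
configuration concern. Defaults: impaired fasting glucose 6.1-6.9 mmol/L,
elevated SBP >= 130 mmHg, elevated triglyceride >= 1.7 mmol/L, low HDL
< 1.0 (men) / < 1.3 (women) mmol/L, overweight 25 <= BMI < 30, obese
BMI >= 30. An Asian overweight option (BMI >= 23) is available, reflecting
the WHO recommendation for Asian populations. All cutoffs are configurable
term parameters.

## Local refits

Local models keep the published term list and re-estimate all coefficients
by maximum-likelihood logistic regression (statsmodels Newton-Raphson,
relative tolerance 1e-10, max 100 iterations, quasi-Newton retry on
non-convergence; separation and rank deficiency raise with the offending
terms named). Wald 95% intervals (estimate +/- 1.96 SE) back the
published-vs-local comparison table; a published effect outside the local
interval is flagged.

Two structural choices mirror the validation workflow:

- **Race coding.** Both a single non-Chinese dummy (Chinese reference, the
  lower-incidence group) and separate Malay/Indian dummies are fitted; the
  lower-AIC coding wins, with both AICs reported. If an ethnicity level is
  absent, the combined coding is used with a warning.
- **Interaction screen.** Each non-ethnicity covariate is tested for a
  covariate-by-ethnicity interaction by a likelihood-ratio test (chi-square,
  df = number of added parameters, keep at p < 0.05). The screen defaults to
  the dichotomous non-Chinese dummy, matching the local models' coding, with
  a three-level option. Kept interactions are self-contained product
  encodings, so the resulting model can score any cohort.

## Recalibration

The external model's slope vector travels; its intercept does not. The
recalibration formula is

    p(x) = 1 - S(m) ^ exp((x - m)' beta)

with `m` the local mean covariate vector on the model's encoding scale
(binary terms contribute their prevalence) and `S(m)` the event-free
probability of the average local subject over the study period. A subject at
the local mean receives exactly `1 - S(m)`; within any stratum the risk
ranking equals the ranking of `(x - m)'beta`.

`S(m)` is the one quantity the formula leaves open, and the package exposes
two estimators:

- `mean_plugin_incidence` (default): `S(m) = 1 - observed incidence`. This
  reads the average subject's survival as the population survival. Because
  `1 - S^exp(d)` is convex in `d` in the relevant range, the *mean* of
  recalibrated risks then exceeds the incidence whenever `(x - m)'beta` has
  appreciable dispersion (a Jensen gap of 1-3 percentage points under the
  default generator), so the plug-in estimator can itself fail
  calibration-in-the-large even when `beta` is perfect.
- `intercept_matched`: solves the one-dimensional monotone equation
  `mean_i [1 - S^exp(d_i)] = incidence` for `S` (Brent root-find,
  tolerance 1e-14), which enforces calibration-in-the-large exactly by
  construction.

Both are reported in comparisons; the transport experiments use
`intercept_matched` because the property being measured *is*
calibration-in-the-large plus goodness of fit, and the plug-in estimator's
Jensen gap would confound coefficient transportability with an estimator
artifact.

### Two-step stratified recalibration

For a population whose ethnic composition does not match the external
model's two-race coding, the two-step procedure first removes the race terms
from `beta` (within an ethnic group the race dummy is constant, so ranking
is unaffected) and then estimates `(m, S(m))` and recalibrates separately
within each ethnic group. Baseline-risk differences between groups are
absorbed into the per-group `S(m)` rather than borrowed from another
population's race coefficient. Age-band stratification works identically
over `pandas.cut` bands (optionally dropping a linear age term), for
populations whose age structure differs sharply from the derivation
cohort's.

Strata must partition the cohort: empty strata raise, a stratum with zero
events gets `S(m) = 1` (all recalibrated risks 0) with a warning.

## Validation metrics

- **AUC**: Mann-Whitney estimator, ties counted 1/2; variance and normal CI
  from the DeLong structural components.
- **DeLong test**: covariance of two correlated AUCs from the per-case and
  per-control structural components; two-sided z test on the difference.
- **NRI**: six clinical categories with bounds 10, 20, 30, 40, 50%
  (half-open: a risk of exactly 0.10 is in the lowest category, matching
  the printed "10.1-20%" labels at their stated precision). Cases moving up
  and non-cases moving down count as improvements; component NRIs are net
  moves over group size, each with the standard asymptotic variance
  `(up + down)/n^2 - (up - down)^2/n^3`; the total NRI's variance is the sum
  of the component variances (independent-components assumption).
- **Hosmer-Lemeshow**: subjects ranked by predicted risk (stable sort, so
  ties keep input order — deterministic) and split into five near-equal
  groups; statistic `sum (O - E)^2 / (E (1 - E/n))`, df = groups - 2 = 3,
  lack of fit flagged above 11.5 (the p < 0.01 point). Degenerate groups
  (E = 0 or E = n) have the variance term floored at a small epsilon and are
  logged. Note the df = 3 reference applies to *fitted* probabilities;
  scoring a cohort with the true generating probabilities spreads the null
  toward chi-square with ~`groups` df, so null rejection at 11.5 is ~1% for
  fitted local models but ~4% for oracle probabilities.
- **Predicted incidence**: `100 * mean(p)`; for an MLE logistic fit this
  equals the observed percentage identically (score equation), which serves
  as an internal consistency check.

## Missing data

Missing follow-up glucose (and any incomplete baseline fields) are
multiply imputed by fully conditional specification: per incomplete field, a
conditional model on the remaining imputer fields, cycled 10 times per
chain, M = 20 independent chains with sub-seeds drawn from one root seed
(bit-reproducible). Continuous conditionals are normal linear models with a
full posterior-predictive draw (scaled-inverse-chi-square variance, normal
coefficient draw, fresh observation noise); binary conditionals are logistic
with a normal coefficient draw; a degenerate conditional falls back to the
marginal rate with a warning.

The imputer field list is wider than any risk model (LDL, hip circumference,
waist-hip ratio, creatinine, insulin resistance enter only as predictors of
missing values) — the inclusive strategy that makes missing-at-random more
plausible.

**Predictive-mean matching** (draw from the 5 observed donors nearest in
predicted mean) is available for continuous fields and is used for
follow-up glucose in the package's own experiments: follow-up glucose is a
case/non-case mixture concentrated around the 7.0 mmol/L diagnostic
threshold, and a plain normal draw misplaces probability mass across the
threshold, biasing downstream coefficients upward by roughly a third of
what the 10%-of-effect tolerance allows; PMM preserves the local shape of
the observed distribution and removes most of that distortion.

Per-imputation coefficient fits are pooled by Rubin's rules: estimate = mean
across imputations, total variance `T = W + (1 + 1/M) B` from the within-
and between-imputation variances. With no missing cells every chain returns
the input and pooling reproduces the complete-data analysis to numerical
precision.

## Synthetic cohort generator

The generator defines the study conditions for every experiment:

- n = 1,401 default; ethnic mix 60/20/20 Chinese/Malay/Indian; 47.8% male.
- Continuous covariates are multivariate normal with the survey's marginals
  (age 36.14 +/- 10.84 y, BMI 22.80 +/- 3.85 kg/m², FPG 5.35 +/- 0.44 and
  HDL 1.26 +/- 0.31 mmol/L, SBP 114.45 +/- 14.58 mmHg) plus field values
  the survey table does not report, set to plausible values for the
  population and era: triglyceride 1.35 +/- 0.75 mmol/L, waist
  74 +/- 9.5 cm, height 162 +/- 8.5 cm (+/- 5.5 cm by sex), 2-hour glucose
  5.6 +/- 1.5 mmol/L. Family-history prevalence 0.355.
- Correlations (marginals only are published): BMI-waist 0.8, FPG-BMI 0.3,
  SBP-age 0.35, FPG-2hPG 0.5, 0.1 elsewhere; the matrix is repaired by
  eigenvalue clipping if indefinite. Values are clipped to plausible
  clinical ranges; latent means are analytically pre-adjusted so the
  *clipped* marginal means still equal the configured ones (clipping the
  age floor at 18 would otherwise shift the mean by ~0.2 y). SDs shrink
  slightly (<~3%) under clipping and are not corrected.
- The outcome is Bernoulli from a configurable logistic model (default: the
  ARIC term structure with its published coefficients) whose intercept is
  root-found on the realized covariates so expected incidence equals the
  7.8% target exactly. A follow-up glucose consistent with the outcome
  (cases >= 7.0 mmol/L) and correlated with baseline glucose and adiposity
  is drawn so that re-deriving the outcome from follow-up measurements
  reproduces it.
- `generate_external_population` shifts covariate means and adds an
  intercept shift *relative to a target-calibrated base model* (the
  intercept is tuned on an independent draw of unshifted covariates, then
  shifted). A log-2 shift therefore doubles the outcome odds at fixed
  covariates, so an external model applied to a base cohort is genuinely
  miscalibrated by the shift — tuning the external intercept on the shifted
  population instead would let the covariate-mean and intercept shifts
  largely cancel and manufacture spurious calibration.
- MAR dropout deletes follow-up glucose with logistic probability on
  *standardized* observed baseline fields (the intercept alone sets the
  marginal rate); a mechanism referencing follow-up fields is rejected as
  missing-not-at-random. True values are retained in `*_true` columns for
  oracle checks. Default mechanism: ~30% missing, loading on age, BMI and
  family history — returners differ systematically from non-returners, the
  pattern reported for the survey.

What the generator does **not** emulate: skewness of triglyceride and
glucose (all covariates are truncated Gaussians), ethnicity-specific
covariate distributions (zero mean shifts by default; ethnic risk
differences enter only through the outcome model's race term),
measurement error, secular drift over the follow-up period, and mortality.
Passing tests therefore demonstrate the *methodology* — estimation,
recalibration, test calibration, imputation — under controlled conditions,
not that any particular published model is well calibrated for a real
population.

## Experiment sizes and numerical choices

The validation experiments (in `riskport.experiments`, also driven by
`scripts/acceptance.py`) use: the worked reclassification example at the
published counts (109 cases, 1,292 non-cases); 200 random instances of
n <= 50 for exact oracle agreement; a 2,000-replicate bootstrap at n = 200
for the DeLong variance; 500 replicates at n = 1,400 for null calibration of
the 11.5 cutoff; 200 replicates at n = 5,000 local / 2,000 external for
transport recovery (mean shifts: age +8 y, BMI +2.5, FPG +0.15 mmol/L,
waist +6 cm; intercept shift log 2); 200 replicates at n = 2,000 for CI
coverage; and 100 replicates at n = 2,000, M = 20 for the imputation study.
The imputation bias is reported for the fasting-glucose coefficient — the
dominant, precisely estimated effect; relative bias on near-zero
coefficients (e.g. triglyceride, 0.0027) is numerically meaningless. At
these sizes the measured pooled-coefficient bias is ~+6% of the generating
value, of which ~+2 points is ordinary MLE small-sample bias present even
without missingness.

Other numerical choices: clinical thresholds are inclusive (>=); quintile
ties break by stable sort; interaction LRTs are floored at zero;
probabilities are computed with exponent clipping at +/-700 to avoid
overflow; all simulation seeds derive from a single integer via
`numpy.random.default_rng` sub-seeding and stay below 2^31.

## Known limitations

- Published-model absolute risks are unavailable without recalibration by
  design (no published intercepts).
- The plug-in survival estimator is reported but not recommended when the
  linear predictor is dispersed; see the Jensen gap above.
- The FCS imputer handles continuous and binary fields; purely categorical
  fields participate as predictors (dummy-coded) but are not imputed.
- The total-NRI variance assumes independent components; the HL epsilon
  guard makes degenerate groups contribute a large but finite term.
- Complete-case logistic fits are consistent when dropout depends only on
  model covariates; the imputation machinery earns its keep when dropout
  tracks variables outside the model, and the experiments are built to
  exercise exactly the harder, mixture-shaped conditional.
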