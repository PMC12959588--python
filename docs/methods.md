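# Methods

## The analysis

`riskhte` implements the risk-modeling approach to heterogeneous treatment
effects (HTE) in a two-arm randomized trial with a binary outcome. Instead of
asking whether a treatment effect differs across levels of one variable at a
time, the workflow stratifies patients by their *predicted baseline
probability of the outcome* — a multivariable summary — and examines how
treatment benefit varies across those risk strata. Four steps, run in order
by `HTEAnalysis.fit()`:

1. **Complete-case filter.** Rows with any missing value among the analysis
   variables (treatment, outcome, all predictors by default; configurable)
   are dropped, with per-variable accounting. No imputation.
2. **Treatment-blinded risk model.** A maximum-likelihood logistic
   regression of the outcome on the baseline covariates only; the allocated
   treatment is deliberately excluded so the model estimates baseline
   prognosis, not treatment response. Continuous predictors enter linearly
   and untransformed; each categorical predictor contributes one indicator
   per non-reference level (reference = first declared level). The model's
   linear predictor LP (log-odds scale) and predicted probability
   expit(LP) feed every later stage.
3. **Interaction test.** A likelihood-ratio test comparing the nested
   logistic models `outcome ~ treatment + LP` and
   `outcome ~ treatment + LP + treatment:LP`, referred to chi-square with
   1 df. The test uses the full continuous LP; the binning of step 4 is
   presentation only, and the test statistic is invariant to affine
   rescaling of LP. The LP is treated as fixed and known — its estimation
   uncertainty is not propagated, and the LP is the in-sample (apparent)
   one, which can be optimistic; this matches the usual single-sample
   application of the workflow and is a documented caveat, not an option.
4. **Strata and benefit.** Predicted probabilities are cut at their
   empirical quantiles (quartiles by default, linear-interpolation quantile
   definition; a patient belongs to the lowest stratum whose half-open
   interval `[low, high)` contains its probability, top interval closed).
   Treatment benefit is the empirical absolute risk difference (RD =
   p_treated − p_control) per stratum, per traditional one-variable
   subgroup (defaults: age dichotomized at 80 years and sex), and overall,
   with unpooled-variance Wald 95% CIs (z = 1.959964) and, for the overall
   effect, a pooled-variance two-proportion z-test. A model-based RD curve
   — the interaction model of step 3 evaluated over LP — is exported
   alongside the empirical stratum RDs, since a benefit-at-mean-risk
   display can reasonably be drawn from either; the package computes both
   and treats the empirical one as primary.

## Numerical choices

- Logistic fits use iteratively reweighted least squares (statsmodels GLM,
  binomial family), deviance tolerance 1e-10, cap 100 iterations. A fit
  whose largest |coefficient| exceeds 15 on the log-odds scale is reported
  as a separation error rather than returned; non-convergence raises an
  error carrying the last iterate. At every converged fit the score vector
  X'(y − p) is numerically zero (tested < 1e-6).
- The c statistic is the Mann–Whitney concordance (ties counted 1/2),
  computed via `sklearn.metrics.roc_auc_score` and verified against
  exhaustive pair enumeration.
- Calibration is summarized by slope (coefficient of LP in a refit) and
  intercept (refit with LP as offset). On the same data the model was fit
  to, these are (1, 0) by construction; they become informative on held-out
  or external data.
- Degenerate inputs fail loudly and specifically: single observed level of
  a categorical predictor, constant continuous predictor, constant LP or
  treatment, fewer observations than strata, and more than half of the
  probabilities tied at one value (quantile strata would collapse) each
  raise a dedicated error. A stratum or subgroup with an empty arm yields a
  flagged, undefined estimate instead of aborting the pipeline.
- Wald/z two-proportion formulas are written directly from their closed
  forms (and cross-checked against `statsmodels.stats.proportion` in the
  tests); no continuity correction, matching conventional trial reporting.
- Density summaries use a Gaussian KDE evaluated on a fixed 201-point grid
  over [0, 1], renormalized after truncation; the overlap coefficient is
  the trapezoid integral of the pointwise minimum of two such densities.

## The synthetic-trial generator

The generator exists so that every pipeline stage is testable without any
data download. It emulates a large thrombolysis trial in acute ischemic
stroke (alteplase vs placebo, favorable outcome = alive and independent at
6 months, prevalence ≈ 35.7%):

- **Covariates** (independent; see limitations): age ~ Normal(78, 10)
  truncated to [18, 100]; sex Male 48.1%; lived-alone, ischemic-change
  assessment, antiplatelet use, atrial fibrillation, GCS eye/motor/verbal
  components and stroke subtype as Bernoulli/categorical with the published
  cohort frequencies; systolic/diastolic BP and weight as normals matched
  on median and IQR (sd = IQR/1.349); total GCS as a discrete integer
  distribution with median 14, IQR [12, 15]; NIHSS as a rounded
  Gamma(shape 1.8, scale 7.1), whose quartiles are exactly the published
  (6, 11, 17).
- **Outcome model**: logit P(Y=1) = LP + T·(β_T + γ·(LP − mean LP)) with
  LP = intercept + Σβ·x. Each covariate coefficient is the log of the
  published odds ratio for that variable (e.g. 0.96/year of age, 0.83/NIHSS
  point). Parameterizing the interaction on the *centered* LP keeps β_T
  interpretable as the effect at average risk and orthogonal to the
  heterogeneity strength γ; γ = 0 is the homogeneous-effect null.
- **Calibrated defaults** (solved once by large-n simulation against the
  emulation targets, then frozen): intercept 5.441 so the overall
  (arm-mixed) favorable-outcome prevalence is 35.7%; γ = −0.295 so the
  expected 1-df LR interaction statistic at n ≈ 3000 has noncentrality
  ≈ 12 (p-values of order 1e-4 to 1e-3, matching the motivating analysis);
  β_T = 0.1106 so the overall risk difference is −1.5 percentage points
  under that γ. Negative γ means patients with high baseline probability
  of recovery are harmed while low-probability patients benefit.
- **Determinism**: one `numpy.random.default_rng(seed)` drives treatment
  assignment, covariates (in declaration order) and outcomes; identical
  (config, seed) reproduces the CSV byte-for-byte. Truncated normals are
  drawn by resampling, so truncation leaves no boundary atoms.
- **Missingness**: `inject_missingness` sets each covariate cell missing
  independently (MCAR) at a given rate; ids, treatment and outcome are
  never touched.

What the generator does *not* emulate — and hence what passing tests do not
establish about real trial data: covariate correlation (real prognostic
variables cluster; independence makes the risk model better specified and
slightly more discriminative than reality), informative or structured
missingness, measurement error, non-logistic outcome mechanisms, and any
deviation from 1:1 independent allocation. Tests against the generator
validate the *statistical machinery* (calibration, coverage, recovery,
contracts), not the clinical conclusions of any particular trial.

## Simulation problem sizes

The shipped validation suite uses: 1000 replicates of n = 2000 for the
null calibration of the interaction test (95% Monte-Carlo band
[0.037, 0.064] around α = 0.05); 150 replicates per point of the power
grid γ ∈ {0, 0.2, 0.4, 0.8}; 250 replicates of the full n = 3035 default
scenario for stratum-CI coverage (band [0.927, 0.973], the nominal level
± Monte-Carlo and small-sample Wald allowance); and 20 seeds of ~50k
control-arm rows for coefficient recovery (each coefficient within 3 SE in
≥ 19/20 seeds). These sizes give Monte-Carlo standard errors a few times
smaller than the widths of the acceptance bands while keeping the default
test run in minutes.

## Analyzing the deposited trial

The pipeline accepts any patient-level CSV conforming to a declared
`VariableSchema`. For the real deposited stroke-trial table,
`examples/ist3_schema.yaml` declares the 15-predictor variable set and
`examples/ist3_mapping.yaml` is a user-editable translation from the raw
export's field names (placeholders — the raw names and the GCS component
codings must be taken from the data dictionary that ships with the
download). With those in hand:

    riskhte analyze --input ist3.csv --schema examples/ist3_schema.yaml \
        --mapping examples/ist3_mapping.yaml --outdir reports/

Because the download cannot be redistributed, the automated tests exercise
this path on a synthetic stand-in and do not assert the deposited trial's
published numbers.

## Known limitations

- Apparent (in-sample) risk model: no cross-validation or shrinkage; with
  many predictors and few events the stratum assignments and the c
  statistic are optimistic.
- Total GCS is modelled alongside its three components, as in the
  motivating variable set; this is near-collinear and the results object
  reports a design condition-number warning when it matters.
- Wald CIs for stratum RDs can undercover with very small strata or
  near-boundary proportions; the operating-characteristics command
  (`riskhte oc`) measures this directly for any configuration.
- The effect-score (treatment-interaction) modelling approach, external
  risk models, ordinal outcome scales and decision-curve analyses are out
  of scope.
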