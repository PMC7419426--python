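# Methods

## Scope and data model

The engine treats one *task* at a time, described by a Common Silica
Process (CSP: task + material + tool), categorical covariates (sector,
project type, environment, region), a sampling duration, a task duration,
and a set of engineering controls. It only estimates exposure for the
worker conducting the task; multi-task 8-h TWA aggregation is the user's
responsibility, and adjacent-worker exposure is addressed only by
boilerplate in the ECP document.

Concentrations are mg/m³ RCS throughout. µg/m³ inputs are converted at CSV
parse time (an explicit `units` column is mandatory — silent unit guessing
is a classic source of 1000× errors in exposure databases).

## Quality control

Six validity criteria gate entry into the modeling database: RCS analyte,
standard analytical method, reported sampling parameters (flow rate,
duration), confirmed original QA/QC, sufficient context to judge
equivalence of operations, and personal (breathing-zone) sampling. Two of
the six — QA/QC and context sufficiency — are curator-asserted booleans:
the underlying judgments (calibration records, field blanks, study design)
are not machine-checkable from a data row, and inventing a proxy rule would
hide the judgment instead of recording it. All criteria are evaluated
independently and every failure reported, so a curator sees the complete
diagnosis per record rather than the first failure.

Respirable-dust-only records fail the analyte criterion. Quartz and
cristobalite measurements are acceptable when polymorph masses and the
sampled air volume allow consolidation to RCS: concentration =
(quartz mass + cristobalite mass) / air volume.

Non-detects are replaced with half the limit of detection. ½ LOD is crude
but standard for modest censoring fractions; the generator's default ~15%
non-detect share is within the range where the resulting bias in log-scale
OLS is small. A maximum-likelihood censored fit is a known improvement and
a deliberate non-goal here.

## De-aggregation of summary statistics

Published aggregates (n with GM/GSD or AM/SD) are expanded into n
pseudo-observations: draw n standard normals, affinely rescale them in log
space to sample mean 0 and sample SD 1 (ddof = 1), then map through
exp(ln GM + ln GSD · z). The empirical GM and GSD of the output therefore
equal the published values to machine precision, which makes downstream
fits reproducible instead of dependent on simulation luck. AM/SD inputs
are first converted assuming lognormality (ln²GSD = ln(1 + SD²/AM²),
GM = AM/√(1+CV²)), the standard occupational-hygiene convention. Edge
cases: n = 1 returns the GM; GSD = 1 returns n copies of the GM.
Pseudo-observations carry a weight field (default 1.0, i.e. equal weight
with true observations) so a down-weighting policy can be applied without
schema changes.

## Exposure model

Ordinary least squares on ln(concentration). The dependent variable is
modeled on the log scale even though the headline quantity is a
concentration: exposure data are lognormal, the ½-LOD rule is
multiplicative, and the Monte Carlo 95th-percentile construction is only
coherent for a linear predictor of log concentration.

Design choices:

* **Duration** enters once, as ln(minutes) by default (configurable to
  linear minutes or dropped). Sampling duration is a proxy for task
  intensity averaging — longer samples average over more low-exposure
  time, hence the negative default effect in the synthetic truth.
* **Reference levels** default to the alphabetically first observed level
  per variable, for determinism; they are configurable, and the synthetic
  module exports the reference set matching its ground truth.
* **Controls** are main-effect indicators. Separation from source is never
  fitted — databases rarely contain enough separated measurements — and is
  instead credited post-hoc as a fixed ×0.75.
* **Parsimony is configuration, not search.** The term list is given
  explicitly; no automated variable selection is performed, so a model is
  exactly reproducible from its formula specification and database version.
* **Minimum cell count** per categorical level defaults to 5 (warning
  below 10). Fitting refuses rank-deficient designs and names the aliased
  terms rather than silently dropping them.
* Fitting is weighted least squares under the per-record weights
  (statsmodels); with all weights 1 this is OLS. Standard errors are the
  conventional OLS/WLS ones.

The fitted object serializes to JSON (schema-versioned) with coefficient
estimates and SEs, reference levels, residual log-SD, fit n, and the
database version stamp; round-trips are bit-exact. The estimator wrapper
follows scikit-learn conventions (`fit`/`predict`/`get_params`, fitted
attributes with trailing underscores) so it composes with sklearn
pipelines; `predict` returns the geometric-mean concentration exp(xβ̂).

## Monte Carlo upper percentile

For a scenario design vector x, each of n_draws (default 1,000) samples
draws every coefficient independently from N(estimate, SE²), forms the
linear predictor, and exponentiates; the reported estimate is the empirical
95th percentile of the draws. Independence across coefficients is a
deliberate simplification — the serialized model carries only marginal SEs
by default, with the full covariance available behind an option. With all
SEs zero the estimate equals exp(xβ̂) exactly, which the tests exploit as a
closed-form oracle; with an intercept-only model the estimate converges to
the analytic lognormal quantile exp(μ + 1.645σ).

This distribution reflects *coefficient* uncertainty, not within-scenario
measurement variability. A flag (`include_residual`) adds a residual draw
N(0, σ̂²) per sample, turning it into the predictive distribution of a
single new measurement; the default is off for scenario assessment and on
inside the validation routine, where the comparison target is the spread
of individual measurements.

Adjustments are applied to the controlled estimate in a canonical order —
fitted control terms (inside the regression), separation factor (×0.75),
short-duration discount (×0.5 strictly below 4 h) — each at most once, with
audit flags recording application. The discount is applied before the OEL
comparison and respirator selection. The uncontrolled estimate is reported
without the discount so the pre/post contrast isolates the effect of
controls. Scalar multiplication commutes, so the order is an audit-trail
convention, not a numerical one.

Respirator selection: hazard ratio r = controlled p95 / OEL; r ≤ 1 needs no
respirator; otherwise the least protective class with APF ≥ r from a
configurable ladder (default: half-facepiece 10, full-facepiece 50, PAPR
100, supplied-air 1000). r beyond the ladder sets an escalation flag —
engineering controls must be revisited, not just more PPE. The OEL
(default 0.025 mg/m³) and ladder are jurisdiction configuration.

## Validation routine

`validate_against_measurements` compares the model with a held-out
measurement set per CSP (groups under 3 measurements excluded): modeled GM
(geometric mean of per-record exp(xβ̂)) against empirical GM, and modeled
p95 against the empirical 95th percentile. The modeled p95 pools Monte
Carlo predictive draws (coefficient uncertainty + residual) across the
group's observed covariate patterns, so within-CSP heterogeneity of
determinants widens the modeled distribution exactly as it widens the
measured one. The report carries the mean modeled/measured ratios, the
fraction of CSPs where the modeled p95 is conservative (≥ empirical), and
the Pearson correlation of per-record log predictions vs log measurements.
Applied to data simulated from the fitted model itself, the GM ratio is ≈1
and the p95 comparison is mildly conservative by construction (coefficient
uncertainty inflates the modeled tail) — the acceptance script measures
both.

## Synthetic data

The generator draws covariates from configurable level frequencies,
controls as independent Bernoulli indicators, duration log-uniform on
60–480 min, and concentration as exp(xβ_true + ε). The default ground
truth mirrors a construction-sector database: 24 CSP levels with effects
spanning roughly e^±1, three sectors, three project types, four
environments, three regions, four controls with negative effects (−0.5 to
−1.0 on the log scale, i.e. reductions to 35–60% of uncontrolled),
baseline GM 0.05 mg/m³, residual log-SD 0.8 (GSD ≈ 2.2), and an LOD of
0.0078 mg/m³ — the marginal 15th percentile of the generated
concentrations, so about 15% of records arrive as non-detects. Values
below the LOD are *flagged*, not substituted, so the QC layer's ½-LOD rule
is exercised on realistic input.

What the generator does **not** emulate: real exposure magnitudes per CSP
(effects are drawn from a fixed pseudo-random spread, not literature),
between-worker/within-worker variance components, correlated control
adoption, reporting heterogeneity across sources, or measurement-method
bias. Passing tests therefore demonstrate statistical correctness of the
machinery (recovery, coverage, calibration) under the model's own
assumptions — not predictive validity for any real population, which
requires the model-vs-measured routine on actual data.

A second fixture generator plants exactly one QC failure per criterion
plus fully passing records, giving tests exact expected counts.

## Problem sizes and numerics

Default problem sizes were chosen to keep every check sharp at desk scale:
parameter-recovery coverage uses 200 replicates of n = 1,000 (≈ 38 fitted
terms, ≈ 25 observations per CSP level); the validation self-check fits on
n = 4,000 and validates on n = 2,400 (≈ 100 per CSP); the MC-vs-analytic
oracle uses 200,000 draws (~0.25% sampling error on the 95th percentile,
against a 1% tolerance). De-aggregation and serialization checks are exact
to 1e-9 or bit-exact. All randomness flows through explicitly seeded
`numpy.random.default_rng` streams; no global state.

## Known limitations

* ½-LOD substitution and independent coefficient draws are simple,
  documented approximations; censored-likelihood fitting and full
  covariance sampling are natural upgrades (the model document already
  reserves a covariance field).
* Main effects only; no control × CSP interactions.
* The short-duration discount is a crude step function inherited from
  regulatory practice, and is flagged as such in the audit trail.
* ECP rendering targets content, not typography: deterministic text/HTML,
  no PDF.
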