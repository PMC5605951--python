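# Methods

## Model

The generator treats a cleaned cohort table as a draw from a simple
parametric model and simulates new rows from the fitted model:

* **Continuous measurements** (height, sitting height, waist, hip, weight,
  systolic/diastolic blood pressure, pulse — 56 columns across nine clinic
  waves in the bundled schema) are modelled as jointly multivariate normal
  after z-scoring. Only first and second moments are preserved: skewness,
  kurtosis, and any non-Gaussian tail behaviour of the real measurements
  are deliberately not reproduced. No transformation toward normality is
  applied to non-normal columns; the synthetic marginals are Gaussian
  approximations of the source marginals.
* **Sex** is modelled conditionally on all continuous columns through a
  logistic regression (codes 1 = male, 2 = female mapped to 0/1, so the
  modelled probability is that of being female). Simulating sex *after*
  the continuous block preserves both the sex proportion and, indirectly,
  the sex-measurement associations that the linear predictor captures.
* **BMI** is a deterministic identity, `weight/(height/100)²`, computed
  from the synthetic same-wave columns. This keeps the identity exact in
  the output (the multivariate normal could only approximate it).
* **Exact ages** are drawn independently per clinic from
  `N(mean, variance)` of the source ages in years. Ages in the source are
  recorded in months and divided by 12 exactly once, at estimation time.
  Independence is a modelling simplification: in a real cohort a child who
  attends one clinic late tends to attend the next one late too.

## Estimation

* Complete-case analysis: any row with a missing value in any schema
  column is dropped before estimation. No imputation.
* Sample statistics use the n−1 denominator (mean/SD/covariance), matching
  the conventions of the statistical environment the procedure is
  typically scripted in, so parameter files are comparable across
  implementations.
* The correlation matrix is the sample covariance of the z-scored block,
  which equals the sample correlation of the raw block. If any eigenvalue
  falls below 1e-10 the spectrum is clipped at 1e-10, the matrix rebuilt,
  and the diagonal rescaled to one ("PSD repair"), so that a Cholesky
  factor always exists. For the bundled fixture the empirical matrix is
  comfortably positive definite and the repair is a no-op.
* The logistic fit uses iteratively reweighted least squares with a ridge
  penalty of 1e-6 on the slopes and none on the intercept, step-halving to
  keep the penalised deviance non-increasing, and a convergence tolerance
  of 1e-8 on the largest coefficient update (at most 100 iterations). The
  ridge exists because BMI is an exact function of height and weight and
  the design is otherwise strongly collinear across waves; at 1e-6 it
  perturbs well-conditioned fits by far less than the 1e-6 agreement the
  test suite demands against an independent GLM implementation. If the
  converged fit classifies the training rows perfectly, the unpenalised
  maximum-likelihood estimate does not exist (complete separation) and the
  fit is refused rather than returned, since its scale would be set by the
  ridge alone.
* The predictor set defaults to *all* continuous columns — measurements,
  BMI and ages — and can be restricted to the measurement block
  (`sex_predictors="mvn_only"`). With 70 predictors on ~1,600 rows the fit
  is quasi-separated (most fitted probabilities hug 0 or 1); this is a
  property of the data, not a numerical failure, and the ridge keeps it
  finite.

## Simulation

* One master seed per dataset; fixed per-stage offsets (continuous block =
  seed, sex = seed + 1, age column *i* = seed + 10 + *i*) make each stage
  independently reproducible. Identical `(params, schema, n, seed)` yields
  byte-identical CSV output.
* Factorisation is Cholesky on the repaired matrix, with an
  eigendecomposition square root as fallback for PSD but rank-deficient
  matrices.
* Tail draws are not truncated: a synthetic child can have a (physically
  impossible) negative weight in the extreme Gaussian tail. The generator
  counts and logs such values (typically ~1 per 10⁵ rows under the bundled
  fixture) instead of clipping, because clipping would bias the moments
  the method promises to preserve.
* CSV output is written with shortest round-trip double formatting, LF
  line endings and the schema's column names verbatim.

## Validation tolerances

All pass/fail thresholds are 4-standard-error Monte-Carlo bounds, not
study constants: standardized mean differences against
`4/√n_syn + 4/√n_src`; relative SD differences against 2 %; pairwise
correlation differences of the jointly-simulated block against 0.02; sex
proportion against 0.01; BMI identity violations against zero. The 2 % /
0.02 / 0.01 bounds are calibrated for synthetic samples of ≥ 100,000 rows;
for smaller outputs they are widened by √(100000/n_syn), since sampling
error scales as 1/√n (disable with `small_sample_scaling=False`). Below
1,000 synthetic rows the pipeline skips moment validation with a warning —
the bounds are too wide to mean anything. All tolerances are configurable.

## The fixture: what it emulates, and what it does not

The real source cohort is access-controlled, so the package ships a
generator of an *emulated* source: 15,445 children, the 71-column schema,
plausible growth-curve means and SDs per clinic, within-trait correlation
decaying as ρ_kind^Δage (AR(1)-style; ~0.97/year for height, ~0.8/year for
blood pressure), cross-trait correlations at equal age, additive sex
shifts (girls slightly ahead through early puberty, boys taller and
heavier by 15–17), and clinic attendance probabilities that decline with
age. Cross-trait cross-wave correlation is the separable form
`C[k,l]·√(ρ_k ρ_l)^Δage`; the implied 56×56 matrix is strictly positive
definite (smallest eigenvalue ≈ 0.002) under the defaults, and a
materially non-PSD user configuration is rejected before sampling. All
numbers are invented defaults with realistic magnitudes — the governed
source publishes no moments — and every one is overridable.

The exact complete-case count (1,593) is produced by a deterministic
completion mask — a fixed-size random subset of rows is left fully
observed, every other row gets at least one missing value (one is forced
if the attendance draws produce none). This makes the count an exact,
testable target instead of a probabilistic one, and makes the
`scripts/acceptance.py` count seed-invariant.

Passing moment-preservation tests on the fixture shows the pipeline
propagates first and second moments correctly through
standardisation, factorisation, sampling and rescaling. It does *not*
show that real cohort data are well approximated by a multivariate
normal — the fixture's continuous block is Gaussian by construction
(up to the sex-shift mixture), so the model is well-specified there in a
way it will not be on real skewed measurements.

## Known limitations

* **Sex-proportion transfer bias.** The sex model's in-sample mean fitted
  probability equals the source proportion exactly (the intercept's score
  equation), but applied to synthetic predictors — a single Gaussian
  standing in for the source's two-sex mixture, with an overfitted,
  quasi-separated linear predictor — the expected proportion shifts
  systematically by ~0.003–0.012 depending on the source realisation. Under
  the fixture defaults the shift is ~0.005 at n = 155,000, inside the 0.01
  bound, but the margin is structural, not statistical: a different source
  draw can push it over. A larger ridge or the `mvn_only` predictor set
  shrinks the bias at the cost of a weaker sex-measurement association.
* Higher-order structure (skewness, non-linear dependence, growth-curve
  dynamics, sibling clustering) is not preserved by design.
* The BMI columns' means/SDs are reproduced only approximately (the
  identity is applied to Gaussian height/weight), though well within the
  validation bounds at the bundled settings.
* The fixture's missingness is structural (attendance draws plus a
  completion mask), not a behavioural model of clinic attendance.

## Problem sizes used by the test suite

The bundled release profile (15,500 / 155,000 / 1,550,000 rows) is
exercised end-to-end once; moment-preservation and recovery checks run at
100,000–155,000 rows, where the 4-SE bounds are tight enough to detect a
real defect; property tests use small vectors. These sizes are the
package's own test design choices and can all be scaled via the public
APIs.
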