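# Methods

## Model and estimands

`trialcal` targets two-arm randomised trials with a continuous endpoint.
The true endpoint follows

    Y = α_Y + β_Y X + γ S + ε,     ε ~ N(0, σ²) iid,

with X ∈ {0, 1} the allocated treatment, S an optional binary prognostic
factor (γ = 0 unless set), and β_Y the estimand: the difference in mean
endpoint between the arms. Allocation in all simulators is a deterministic
equal split (n per arm), reflecting block-randomised trials; S is drawn iid
Bernoulli(p), independent of X, so its prevalence is equal in both arms in
expectation.

The observed endpoint Y\* is generated by one of five error structures
(classical, heteroscedastic, systematic, differential, covariate-additive;
see the `datagen` module docstring for the formulas). The naive analysis is
the OLS regression of Y\* on X. Its probability limit and residual SD under
each structure are available in closed form (`expected_naive_slope`,
`expected_residual_sd`) and are used both to parameterise scenarios and as
analytic oracles in the tests.

## Calibrating the error SD from R²

Scenario strength is specified through the squared correlation R² between
Y\* and Y **within a treatment arm** (equivalently, the coefficient of
determination of the calibration regression at fixed X):

    R² = θ₁²σ² / (θ₁²σ² + τ²)   ⇒   τ = |θ₁| σ √((1 − R²)/R²).

The conditional convention matters: defining R² against the marginal
variance of Y (which includes the treatment-effect spread) would give
different, larger τ values for the same nominal R². With σ = 12.6 this
calibration gives τ = 6.615/13.23/26.46 for θ₁ = 1.05 at R² = 0.8/0.5/0.2,
τ = 7.875 for θ₁ = 1.25 at R² = 0.8, and 6.3/12.6/25.2 for a unit slope —
the values used throughout the preset grids (one-decimal roundings appear
in the scenario names).

## Corrected estimators

With an external calibration sample (K subjects outside the trial with both
Y and Y\* measured; OLS of Y\* on Y giving θ̂₀, θ̂₁ and, for differential
error, per-arm fits from a two-arm pilot design):

* systematic:  α̂_Y = (α̂_Y\* − θ̂₀)/θ̂₁,  β̂_Y = β̂_Y\*/θ̂₁
* differential: α̂_Y = (α̂_Y\* − θ̂₀₀)/θ̂₁₀,
  β̂_Y = (β̂_Y\* + α̂_Y\* − θ̂₀₁)/θ̂₁₁ − α̂_Y

**No truncation.** The corrected effect is a ratio; when K is small and R²
low, θ̂₁ lands near (or below) zero with non-negligible probability and the
ratio explodes or flips sign. These heavy tails are a genuine property of
the estimator and are propagated as-is — the Monte-Carlo tables are *meant*
to show them. Only an exactly zero estimated slope raises an error (and is
counted, not fatal, inside the engine).

Trial OLS uses the closed-form two-group solution (slope = difference of
arm means), which is exact and an order of magnitude faster than generic
least squares inside the replication loop. The covariate-conditional
analysis uses a generic small-design OLS path that silently drops a
constant covariate column, so a zero-prevalence prognostic factor degrades
to the unadjusted analysis rather than erroring.

For the differential pipeline the trial variance is always the HC3
leverage-adjusted sandwich (per-arm residual variances differ by
construction there); for the systematic pipeline the model-based OLS
variance is the default, since that structure leaves the residuals
homoscedastic.

## Confidence intervals

All four constructions treat the trial fit and the calibration fit(s) as
independent (they come from disjoint samples).

* **Zero-variance**: Var(β̂_Y) with all θ̂ treated as known constants —
  systematic: Var(β̂_Y\*)/θ̂₁²; differential: a²Var(α̂_Y\*) + b²Var(β̂_Y\*) +
  2ab·Cov with a = 1/θ̂₁₁ − 1/θ̂₁₀, b = 1/θ̂₁₁ (HC3 trial block).
  Anti-conservative by construction; kept as a floor and a diagnostic.
* **Delta**: first-order Taylor variance. Systematic:
  Var(β̂_Y\*)/θ̂₁² + β̂_Y\*²Var(θ̂₁)/θ̂₁⁴. Differential: the full gradient of
  the corrected effect in (α̂_Y\*, β̂_Y\*, θ̂₀₀, θ̂₁₀, θ̂₀₁, θ̂₁₁) applied to the
  block-diagonal joint vcov (trial HC3 block; per-arm calibration OLS
  blocks including intercept–slope covariance). Validated in the tests
  against numerical differentiation.
* **Fieller** (systematic only): bounds are the roots in ρ of
  (β̂_Y\* − ρθ̂₁)² = t²(Var(β̂_Y\*) + ρ²Var(θ̂₁)). The confidence set is a
  bounded interval iff θ̂₁² > t²Var(θ̂₁), i.e. the calibration slope is
  significantly non-zero at the working quantile; otherwise the result is
  flagged undefined — a legal outcome the engine counts, never an
  exception. When defined, the interval always contains β̂_Y\*/θ̂₁.
* **Percentile bootstrap**: B resamples (default 999) drawing trial rows
  with replacement within each arm (allocation is fixed by design) and
  calibration rows independently (within each arm for differential);
  the corrected estimate is recomputed per resample and the interval is
  the (α/2, 1 − α/2) percentile pair. Resamples whose calibration draw is
  degenerate (constant Y, or exactly zero slope) are dropped and the
  effective B reported; negative resampled slopes are retained, consistent
  with the no-truncation policy. Percentile rather than BCa intervals are
  used; BCa is a possible extension that would reduce the slight
  conservativeness at small K.

Quantile convention: t with N − 2 degrees of freedom for the zero-variance
and delta intervals and for the Fieller quadratic — the trial fit dominates
the variance, and N − 2 is the natural df of its slope. Using the
calibration df (K − 2) instead would widen intervals noticeably only for
K ≤ 10; the choice is exposed through the `alpha`/fit arguments rather than
hard-coded magic numbers. Bootstrap quantiles use the default linear
interpolation of `numpy.quantile`.

## Monte-Carlo engine

Each replication draws a fresh trial and a fresh calibration sample,
computes naive and corrected analyses with the requested intervals, and the
engine aggregates percentage bias, empirical SE, √MSE, per-method coverage,
average width, and Type-II error (Type-I when the generating effect equals
the null), each with its Monte-Carlo standard error:

* MCSE(bias) = EmpSE/√R, MCSE(EmpSE) = EmpSE/√(2(R−1)),
* MCSE(coverage) = √(c(1−c)/R), MCSE(MSE) = SD(squared errors)/√R.

Fieller coverage and width are computed over defined intervals only and
suppressed entirely (reported NaN) when the undefined rate exceeds 5% —
averaging a selectively defined interval against always-defined competitors
would be misleading.

Reproducibility: replication r of a scenario with seed s uses the dedicated
substream `SeedSequence(s, spawn_key=(r,))`. Results are therefore
invariant to execution order, any single replication can be replayed in
isolation, and identical configuration + seed gives bit-identical
summaries. Replications are statistically independent and could be
distributed; the shipped engine runs them sequentially.

## Preset scenarios and problem sizes

The preset grid (`preset_scenarios`) fixes the generating model at
α_Y = 120, β_Y = 6.9, σ = 12.6 (haemoglobin in g/L), N = 400 split equally:

* systematic grid: θ₁ ∈ {1.05, 1.25} with R² as above,
  K ∈ {5, 7, 10, 15, 20, 30, 40, 50}, placebo-characteristics calibration;
* differential grid: θ₁₀ = 1, θ₁₁ = 1.05, per-arm τ from the same R²
  levels, K ∈ {10, 20, 30, 40, 50} split equally over arms (two-arm pilot
  design — a placebo-only calibration cannot identify arm-specific error);
* prognostic-factor scenario: Y = 120 + 6.9X + 10S + ε with P(S=1) = 0.75,
  Y\* = Y + 0.5S + e with SD(e) = 6.6. Note the error term is parameterised
  by its SD: with SD(e) = 6.6 the analytic between-replication variances of
  the unadjusted and S-conditional estimators are 2.23 and 2.02, which the
  simulation reproduces; interpreting 6.6 as a variance would not.
* illustrative small-trial presets (54 per arm, powered for ~20% Type-II
  error without error): classical error with τ = 18.1, i.e. a 75% inflation
  of the observed-endpoint SD (12.6 → 22.05) and hence a ~3× increase in
  the between-replication variance of the estimate. These presets are
  illustrative only and none of the benchmark quantities are computed from
  them.
* null-effect variants (β_Y = 0) for Type-I checks.

Default replication counts: 10,000 per scenario. The acceptance script
(`scripts/acceptance.py`) uses 10,000 replications for every quantity
except the bootstrap-coverage run (5,000 replications × 999 resamples,
chosen as the point where the coverage MCSE of ~0.3 percentage points is
small relative to the quantity's interpretation). The test suite reruns
scenarios at 1,500–4,000 replications and compares with tolerances of three
combined MCSEs.

## What the generators do and do not emulate

The synthetic data realise exactly the assumptions of the model: normal
residuals, error independent of everything except as parameterised, linear
error structures, perfectly balanced allocation, a calibration sample drawn
from the same population as the trial's control arm (or both arms). Passing
tests therefore demonstrate the estimators' behaviour *under the model*,
not robustness to what real trials add: non-normal or skewed endpoints,
error that grows in the tails, calibration samples from a different
population than the trial, missing data, or more than two arms. Measurement
error in the treatment indicator or in covariates is out of scope, as are
internal-calibration designs (both endpoint versions measured on a subset
of trial participants) and multiple-imputation-style corrections.

## Known limitations

* The corrected estimators have no finite moments in the strict sense (the
  denominator is normal around θ₁); reported EmpSE/MSE at small K and low
  R² are draws from a heavy-tailed distribution and vary strongly between
  seeds. This is faithful to the method, not a defect of the engine.
* The delta and zero-variance intervals rely on asymptotic normality of
  the ratio; at K ≤ 10 they under-cover, as the Monte-Carlo tables show.
* The Fieller construction is implemented for the systematic structure
  only; the differential corrected effect is not a simple ratio of two
  estimates, so no analogous exact inversion is offered.
* CSV inputs must be complete; no missing-value handling is provided.
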