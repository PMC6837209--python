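# Methods

## The data-generating model

Each simulated participant *i* in exposure group *g* (0 = unexposed,
1 = exposed) has

- a true baseline telomere length `LTL_b_i ~ N(mu_b_g, sd_b_g)` in bp,
- a true annual change `delta_i ~ N(mu_d_g, sd_d_g)` in bp/yr, drawn
  independently of baseline (true attrition does not depend on true
  baseline length — an explicit modelling assumption),
- a true follow-up length `LTL_fu_i = LTL_b_i + T * delta_i` for a
  follow-up interval of `T` years, i.e. change is constant within person.

Measurements add independent normal error at each time point:
`mLTL_x = LTL_x + e_x` with `sd(e_x) = LTL_x * CV/100` (proportional mode)
or a fixed bp value (additive mode). Measured per-year change is
`mdelta_i = (mLTL_fu_i - mLTL_b_i)/T`.

Because `mLTL_b` is a common effect of `LTL_b` and `e_b`, and `e_b` enters
`mdelta` with a negative sign, `mLTL_b` is a collider between exposure
(associated with `LTL_b`) and measured change. Unconditionally, exposure
and `mdelta` are independent when the true rates are equal; conditioning on
`mLTL_b` (models 2 and 3) opens the path and produces a negative spurious
exposure effect whose magnitude grows with both the assay error and the
baseline group difference.

## Scenario presets and default parameters

Parameters are anchored to a Southern-blot smoking cohort with very low
assay error (inter-assay CV 1.4%), so the published moments are close to
true values:

| parameter | default | units |
|---|---|---|
| baseline mean (no group difference) | 7430 | bp |
| baseline sd (both groups) | 777 | bp |
| annual change sd (both groups) | 46 | bp/yr |
| shared annual change (null scenarios) | −40.7 | bp/yr |
| group annual changes (effect scenarios) | −40 / −42 | bp/yr |
| baseline group difference (C, D) | 141 (7500 vs 7359) | bp |
| follow-up interval | 10 | yr |
| group sizes | 1000 / 1000 | — |

Scenarios: **A** no baseline difference, no attrition difference; **B**
attrition difference only; **C** baseline difference only; **D** both.
**REV** is a direction-reversal scenario (parameters not published; chosen
here as the C baseline deficit with the attrition difference mirrored:
exposed −40, unexposed −42 bp/yr, a true +2 bp/yr effect) in which baseline
adjustment first cancels and then reverses the true effect as CV grows.
For C/D the unexposed mean is anchored at 7500 bp and the exposed mean is
`7500 − baseline_diff`, which reproduces the published 7500/7359 pair
exactly and makes the zero-difference limit exactly symmetric.

Assay CVs of 0–16% are simulation-internal knobs; they are not directly
comparable to laboratory-reported CVs (different zero points), which is why
the signatures module maps CV onto data-internal correlations instead.

## The four models and their numerical treatment

Models 1–3 are ordinary least squares (statsmodels OLS), with two-sided t
tests; "significant" means p < 0.05 throughout. Exposure is coded 0/1 so a
negative coefficient means faster attrition in the exposed group. Model 3's
raw coefficient (bp over the interval) is divided by `T` so all models share
bp/yr units; this requires a constant interval and is exactly equal to
model 2's coefficient because the two outcomes differ by a linear function
of the covariate.

Model 4 is the random-intercept mixed model `mLTL ~ timepoint * exposure +
(1 | participant)`. With exactly two time points and complete balance the
GLS fixed effects do not depend on the variance components: the interaction
equals the difference-in-differences of cell means (hence exactly the
change-score estimate), and its standard error involves only the residual
variance, estimated from the within-participant change regression. The
default engine computes this closed-form solution; a numeric statsmodels
MixedLM engine is retained and cross-checked in the tests. Inference for
the interaction uses the asymptotic normal test; exact small-sample
degrees-of-freedom corrections are out of scope since all conclusions rest
on p < 0.05 at n ≥ 200.

Standardized coefficients z-score both the outcome and the 0/1 exposure
indicator (equivalently, beta_std = beta * sd(x)/sd(y)); the published
summary table does not define its standardization, and this is the
convention that makes the coefficient invariant to rescaling the telomere
measurements. An exactly-zero coefficient standardizes to 0 even when the
outcome is degenerate.

## Regression-to-the-mean correction (D)

The corrected change is computed within each exposure group from observed
moments only:

    D_i = (mLTL_fu_i − mLTL_b_i) + (1 − r_g) (mLTL_b_i − mean_g(mLTL_b)),

with `r_g` the group's Pearson correlation between baseline and follow-up
measurements, reported per year. Two properties motivated this form over
the pooled regression-slope variant. First, a pooled correction that adds a
linear function of `mLTL_b` cannot change the baseline-adjusted model at
all (the covariate absorbs it) and *does* shift the unadjusted contrast
whenever group baselines differ, which contradicts the correction's
documented behaviour. Second, the within-group form leaves every group mean
of change untouched, so the change-score estimate is exactly invariant,
while the adjusted model acquires a small *positive* residual bias at low
CV (the correlation subsumes true change variance, not only error) that
decays toward zero as error grows — the behaviour this correction is known
to produce. The correction is supported for models 1 and 2; models 3 and 4
are redundant with them and are dropped from the corrected analysis.

## Monte-Carlo grids

Per (scenario, error level) cell the engine simulates `n_replicates`
datasets and fits all requested models to the same replicates, so model
contrasts are paired. Replicate seeds derive from
`SeedSequence([grid_seed, scenario_index, cv_index, replicate])` masked to
31 bits, making every cell reproducible in isolation and independent of the
model list and execution order. Cell summaries report the mean estimate, a
normal-approximation 95% CI of the mean (mean ± 1.96 sd/√reps — the
construction behind published replicate-mean error bars is not stated, and
replicate means at these counts are effectively normal), and the proportion
of replicates with p < 0.05 (type-I error under a true null, power
otherwise). Replicate fit failures are logged with their seed and excluded;
more than 1% of failures aborts the cell.

Default replicate counts: full surfaces use 1000 replicates; the packaged
verification runs use 200–500 replicates with 3-sigma Monte-Carlo bands,
which resolves every qualitative and quantitative contrast asserted (the
smallest asserted effect, the D-corrected adjusted-model bias of ~+2 bp/yr,
is ~12 standard errors at 200 replicates) while keeping the whole suite
around half a minute.

## Error signatures

`r(mLTL_b, mLTL_fu)` shrinks toward 0 and `r(mLTL_b, mdelta/yr)` becomes
more negative as error grows; the slope of follow-up on baseline is ≤ 1
(attenuation). Per-participant intervals come from ages when present, so
user cohorts may have varying follow-up. Cohen's *d* for the baseline
group difference uses the group-size-weighted pooled sd. All five
statistics are invariant to rescaling the measurements, which is what makes
them comparable across assay technologies with different units.

## Meta-analysis layer

Across cohorts the package regresses one summary statistic on another by
weighted least squares with weights equal to the total number of
participants per cohort (the convention of the published analysis; inverse-
variance weighting is deliberately not used), with t inference on
n_cohorts − 2 df; paired comparisons of the two models' standardized
coefficients use the classic paired t-test. Per-cohort significance of
individual coefficients is deliberately not reported: the cohorts are small
and the point of the layer is the systematic shift, not per-cohort claims.

The built-in reference table carries the published two-decimal summaries of
seven cohorts; the meta-regression slopes recomputed from it (0.896, 0.740,
0.115) differ from the published ones (0.89, 0.76, 0.11) only through that
printed rounding.

The synthetic multi-cohort generator emulates the reference table's
structure: a fixed 141 bp true baseline deficit, zero true attrition
difference, per-cohort CV uniform on a requested range, total sizes uniform
on a range matching the published 47–539 span, exposed fraction uniform on
0.1–0.5 and an 8.5-year interval (the published mean). One caveat it makes
visible: each synthetic cohort's Δβ is proportional to its *realized*
sample baseline difference, whose sampling sd at these cohort sizes is
comparable to the 141 bp signal, so a single 7-cohort draw recovers the
positive Δβ-vs-r(b,fu) slope only ~70–80% of the time; the relationship is
therefore asserted on the mean over many seeded repetitions. Real cohorts
with larger baseline contrasts (|d| up to 0.99) carry proportionally more
signal.

## What the generator does and does not emulate

Emulated: group-structured baselines and attrition rates, proportional or
additive assay error independent across time points, heterogeneous cohort
sizes and error levels. Not emulated: age-dependent or non-normal attrition,
more than two time points, within-person error correlation (batch effects),
dropout, covariates such as age/sex/race (the exposure flag is generic, so
other binary exposures are covered by relabelling, but continuous exposures
are not). Passing tests therefore demonstrate the collider mechanism and
estimator behaviour under these idealized conditions, not the full
messiness of real cohort data.

## Degenerate inputs and conventions

Fewer than 2 participants in either group, zero-variance covariates or
outcomes, non-positive intervals and malformed CSVs raise ValueError with
the offending margin named; mixed-model non-convergence raises a distinct
error type. A paired t-test on identical vectors reports t = 0, p = 1. CSV
round trips are bit-exact (shortest-repr floats on write, round-trip float
parsing on read).
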