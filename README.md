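# telosim

Simulation and meta-analysis toolkit for a methodological question in
telomere epidemiology: **should longitudinal analyses of telomere attrition
adjust for baseline telomere length?**

Longitudinal studies measure leucocyte telomere length (LTL, in base pairs)
at baseline and follow-up and ask whether an exposure (smoking is the
canonical example) accelerates attrition, the per-year change
ΔLTL = (LTL_fu − LTL_b)/interval. Nearly all published analyses include the
*measured* baseline mLTL_b as a covariate. But mLTL_b is a common effect of
true baseline length and baseline measurement error — a **collider**. When
the exposed group truly starts with shorter telomeres and the assay has any
error, conditioning on mLTL_b opens a spurious path between exposure and
measured change (regression to the mean), biasing the estimated exposure
effect away from zero. `telosim` quantifies that bias.

## What it does

- **Simulate cohorts** (`telosim.simcohort`): two-timepoint cohorts of
  smokers/non-smokers with group-wise normal baselines and constant annual
  change, plus proportional (CV%) or additive (bp) assay error at each
  time point.
- **Fit the four standard models** (`telosim.models`), harmonized to bp/yr:
  1. change score: mΔLTL ~ smoking (two-sample t-test)
  2. ANCOVA on change: mΔLTL ~ mLTL_b + smoking
  3. ANCOVA on follow-up: mLTL_fu ~ mLTL_b + smoking
  4. repeated measures: mLTL ~ timepoint × smoking, random intercept per
     participant
  plus the Verhulst-style regression-to-the-mean-corrected change score *D*.
- **Map bias / type-I-error / power surfaces** (`telosim.experiment`) over
  scenario × CV × model Monte-Carlo grids, with sensitivity axes for
  baseline difference, sample size, effect size, additive error, the
  *D*-corrected outcome and a direction-reversed scenario.
- **Compute measurement-error signatures** (`telosim.signatures`): the
  correlations r(mLTL_b, mLTL_fu) (attenuated by error) and
  r(mLTL_b, mΔLTL/yr) (pushed negative by error), the corresponding slopes
  and the baseline Cohen's *d*.
- **Meta-analyze cohort summaries** (`telosim.meta`): a built-in table of
  seven published longitudinal smoking cohorts (ADELAHYDE, Caerphilly,
  ERA, Hertfordshire, Lothian 1921/1936, NSHD; 1768 adults), participant-
  weighted meta-regression, paired t-tests, and a synthetic multi-cohort
  generator for end-to-end validation of the Δβ = β₂ − β₁ error signature
  relationship.

## Worked example

Collider bias appearing as assay error grows, in a world where smokers
start 141 bp shorter but truly attrite *no faster* (scenario C):

```python
from telosim import GridSpec, make_scenario, run_grid

g = GridSpec(scenarios=[make_scenario("C")], cvs=[0, 4, 16],
             n_replicates=200, models=(1, 2), seed=7)
print(run_grid(g).to_string(index=False))
```

```
scenario     cv  model  mean_beta  ci_low  ci_high  prop_significant  n_replicates
       C  0.000      1      0.072  -0.199    0.342             0.030           200
       C  0.000      2      0.074  -0.196    0.345             0.035           200
       C  4.000      1      0.078  -0.308    0.464             0.050           200
       C  4.000      2     -1.751  -2.130   -1.372             0.095           200
       C 16.000      1      0.129  -0.848    1.107             0.020           200
       C 16.000      2     -9.983 -10.805   -9.162             0.385           200
```

The change-score model (1) stays centred on the true value, 0 bp/yr, at
every error level and rejects at the nominal 5% rate. The baseline-adjusted
model (2) is unbiased only with a perfect assay; at CV 4% it already
manufactures a −1.8 bp/yr "effect" (comparable to the −2 bp/yr real-world
smoking estimate), and at CV 16% a −10 bp/yr one, with the false-positive
rate rising toward 40% — pure artefact of adjusting for a collider.

The same comparison on the seven published cohorts, from the command line:

```bash
telosim meta --from-fixture --out summaries.csv
```

writes one row per cohort mirroring the published summary table; the
baseline-adjusted coefficients (β₂) are systematically more negative than
the unadjusted ones (β₁) — e.g. Hertfordshire: −0.27 vs −0.12, Caerphilly:
0.12 vs 0.22 — and the shift Δβ = β₂ − β₁ is largest in the cohorts whose
signature correlations indicate the most measurement error.

A CLI also exposes `simulate`, `fit`, `grid`, `sensitivity` and
`signatures`; every subcommand is deterministic given `--seed`.

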