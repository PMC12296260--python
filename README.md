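# rdnat

Regression-discontinuity analysis for natural experiments with discrete
monthly running variables — built around the canonical example of a
school-leaving-age reform assigned by a date-of-birth cutoff, and the
question of whether the extra schooling it mandated changed long-term
brain structure.

`rdnat` is aimed at researchers analysing cutoff-assigned policy reforms
in large observational cohorts (epidemiology, population neuroscience,
economics of education). It provides, as a single tested pipeline:

- **A synthetic cohort generator** that emulates the data structure of a
  birth-cutoff reform: a monthly running variable spanning ±120 months, a
  first-stage compliance jump of ~0.10 at the cutoff, years-of-education
  coding (college completers = 21), standard neuroimaging nuisance
  covariates with ~4% missingness, six correlated global outcomes, and
  correlated regional panels (66 + 66 cortical regions, 27 tracts, 18
  subcortical volumes). Every downstream stage is testable without any
  restricted data access.
- **Continuity-based fuzzy local-linear RD.** With running variable `X`
  (months, centred so the first treated month is 0), assignment
  `Z = 1[X ≥ 0]`, treatment received `D` and outcome `Y`, side-specific
  local-linear fits with triangular kernel weights `w = max(0, 1 − |X|/h)`
  estimate the reduced-form (intent-to-treat) jump `τ_Y` and the
  first-stage jump `τ_D`; the fuzzy estimand is the local average
  treatment effect among compliers,

  `LATE = τ_Y / τ_D`,

  with heteroskedasticity-robust (HC1) intercept variances and a
  delta-method standard error that accounts for the covariance of the two
  jumps. The bandwidth `h` is selected by the Imbens–Kalyanaraman
  regularized MSE-optimal rule for the triangular kernel and shared
  between the two stages, so `τ_Y = LATE × τ_D` holds exactly.
- **Two-step covariate adjustment** (`uY ~ 1 + X + 1[X≥0] + X·1[X≥0] + C′`,
  then `Y = uY − C′β̂*`) applied to both stages to increase precision, plus
  Tukey winsorization (fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR) and
  per-modality Benjamini–Hochberg FDR correction for regional panels.
- **Bayesian local randomization.** Participants born within ω months of
  the cutoff (ω = 1 and 5 by default) are treated as exchangeable and
  analysed with `Y ~ Z + C′` under autoscaled normal priors
  `β ~ N(0, s·sd(y)/sd(x))`, s ∈ {0.5, 1, 1.5}. Evidence for the point
  null is quantified by the Savage–Dickey density ratio
  `BF01 = p(β=0 | data) / p(β=0)` and graded on Jeffreys' scale; a Gibbs
  sampler (validated against the conjugate closed form, rhat < 1.05)
  or a fast analytic conjugate path can be used. Substituting continuous
  years of education for the assignment dummy on the *same* participants
  gives the correlational counterpart, making confounding visible as a
  causal/associational divergence.
- **Validity diagnostics**: an exact binomial bunching (density) test of
  the running variable, placebo outcome tests that run the main
  estimators verbatim on covariates (with automatic exclusion of
  covariates deterministically tied to assignment, e.g. the summer-born
  indicator), and placebo cutoff analyses.

## Worked example

```python
from rdnat import CohortConfig, generate_cohort, FuzzyRD
from rdnat.localrand import itt_analysis

table = generate_cohort(CohortConfig(seed=1))   # null cohort, n = 28,800
covs = ("sex", "summer", "dos", "dos2", "site", "motion", "t2flair")

res = FuzzyRD(table, "SA", first_stage="stayed16", covariates=covs).fit("mse")
print(res.summary())
```

```
Fuzzy local-linear regression discontinuity
===============================================
outcome:          SA
first stage:      stayed16
kernel:           triangular
bandwidth:        63.16 months (imbens-kalyanaraman)
effective n:      6421 left / 6507 right
-----------------------------------------------
reduced form:     -0.03627 (SE 0.03813)
first-stage jump:  0.08732 (SE 0.00798)
LATE:             -0.41534 (SE 0.43842)
95% CI:           [-1.27463, 0.44394]
p (two-sided):    0.3435
```

The first-stage jump recovers the generator's 0.10 compliance jump (0.087
± 0.008 in this draw), the reduced form is a null −0.036 SD, and the
complier effect of a year of schooling is −0.42 SD with a wide CI
straddling zero — no evidence of a discontinuity, as planted. The
Bayesian 5-month window quantifies that null directly:

```python
for entry in itt_analysis(table, "SA", 5, priors=(0.5, 1.0, 1.5),
                          covariates=covs, method="analytic"):
    bf = entry["bf"]
    print(f"prior multiplier {entry['prior'].scale_multiplier:>3}:"
          f"  BF01 = {bf.bf01:6.2f}  ({bf.grade})")
```

```
prior multiplier 0.5:  BF01 =  12.42  (strong evidence for the null)
prior multiplier 1.0:  BF01 =  24.79  (strong evidence for the null)
prior multiplier 1.5:  BF01 =  37.18  (very strong evidence for the null)
```

The same machinery is exposed on the command line (`rdnat simulate`,
`rdnat rd`, `rdnat localrand`, `rdnat validity`, `rdnat regional`,
`rdnat replicate`, `rdnat plot`, `rdnat run-all`), and
`rdnat.run_all(RunConfig(...))` executes the whole preregistration-style
pattern (global + regional continuity, both window analyses, validity
suite, sub-cohort replication) into a `ResultsBundle` of TSV tables with
a provenance manifest.

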