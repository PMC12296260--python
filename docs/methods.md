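# Methods

This note documents the statistical machinery implemented in `rdnat`, the
defaults it ships with, and what the synthetic-data tests do and do not
establish about real data.

## The design being modelled

A policy reform raises the minimum school-leaving age, assigned by a
date-of-birth cutoff: children born on or after the cutoff month had to
stay in school a year longer. Decades later, participants of a large
imaging cohort are scanned; the question is whether the extra year of
education changed brain structure. Two complementary identification
strategies are implemented:

1. **Continuity-based fuzzy RD.** Under the assumption that all potential
   confounders vary smoothly through the cutoff, any discontinuity in the
   conditional mean of an outcome at the cutoff is attributable to the
   reform. Because compliance is probabilistic (most children already
   stayed voluntarily), the design is fuzzy: the reform shifts the
   *probability* of treatment by the first-stage jump (~0.10), and the
   complier effect is the ratio of the outcome jump to that first-stage
   jump.
2. **Local randomization.** Within a narrow window of ±ω months around
   the cutoff, birth timing is treated as as-if random and the
   intent-to-treat contrast is a (Bayesian) regression of the outcome on
   the assignment dummy plus covariates.

## Synthetic cohort generator

The generator (`rdnat.cohort`) defines the study conditions under which
everything is tested:

- Running variable `mdob` ∈ [−120, 119] months, month 0 the first treated
  month; 120 participants per month by default (n = 28,800 overall, ~240
  in the 1-month window, ~1,200 in the 5-month window — the scales of the
  motivating design).
- First stage: `stayed16 ~ Bernoulli(p(m))`, `p(m) = 0.90 + jump·1[m≥0]
  + trend·m` with `jump = 0.10` and `trend = 0` by default, i.e. 90%
  voluntary compliance rising to (near-)universal uptake at the cutoff.
  Compliance is one-sided (the reform only adds schooling), so
  ITT = first-stage jump × complier effect holds exactly in expectation.
  Any trend that pushes `p` outside [0, 1] is rejected with the offending
  month named, rather than clamped.
- Education years derive from the leaving age: 10 years for leavers at
  15, 11 for staying to 16, 13 for A-levels (40% of stayers), and
  college completers are coded 21 years, mirroring how the survey
  question is recorded.
- Outcomes: six global measures sharing a smooth secular trend
  (polynomial `(0, 0.005, 2e-5)` in months, in residual-SD units — a
  mild age/recruitment drift with enough curvature to make bandwidth
  selection non-degenerate), covariate effects (sex 0.5 SD, head motion
  −0.2 SD, scan-date −1e-4 SD/day, small site offsets), an optional
  treatment discontinuity `effect_delta` (per-outcome, units of the
  residual SD; 0 by default), and noise with cross-outcome equicorrelation
  0.6 (global brain measures are strongly correlated in real data).
  With `noise_sd = 0` the outcome is an exact deterministic function of
  month and covariates, which the exactness oracles exploit.
- Regional panels (66 + 66 cortical, 27 tract, 18 subcortical) share the
  secular trend plus equicorrelated region noise (default 0.5).
- Covariates are missing completely at random at 4% per cell (never the
  running variable, assignment, first stage or outcomes).
- An optional latent factor confounds education (via the college-completion
  log-odds) and outcomes without touching assignment; it is the mechanism
  behind the causal-vs-correlational divergence scenario.

What the generator does **not** emulate: volunteer/selection bias in who
gets scanned, informative missingness, genetic confounding, realistic
joint covariate distributions (covariates are independent), or any
spatial structure beyond equicorrelation. Passing tests therefore show
that the estimators are correct and calibrated *under the stated
sampling model*, not that the design assumptions hold in any particular
real cohort.

The summer-born indicator is a deterministic function of birth month and
deliberately has no outcome effect in the defaults: a nonzero effect of a
month-deterministic covariate would place a real discontinuity at the
cutoff and contradict the null design.

## Continuity-based estimation

- **Kernel and fits.** Triangular weights `max(0, 1 − |x|/h)`; weighted
  least squares of `y ~ 1 + x` separately on `x < 0` and `x ≥ 0`; the
  jump is the difference of fitted intercepts. Variances are HC1 per
  side (verified against statsmodels' WLS to machine precision); the
  reduced-form/first-stage covariance is computed from the shared
  per-observation influence weights, and the LATE standard error follows
  by the delta method. p-values use the normal reference (effective n is
  in the thousands in intended use).
- **Bandwidth.** The Imbens–Kalyanaraman first-order MSE-optimal rule
  for the triangular kernel (constant 3.4375): a Silverman-style pilot
  window gives the outcome variance and running-variable density at the
  cutoff; a global cubic supplies the third derivative that scales the
  curvature-pilot windows; side-specific local quadratics give the second
  derivatives; regularization terms `2160·σ²/(N₂·h₂⁴)` guard against
  near-zero curvature differences. The selector is affine-invariant in
  the outcome and equivariant under rescaling of the running variable
  (both tested to 1e-8), deterministic, clamped to the data half-range,
  and floored at 3 months (minimum support for two-sided linear fits).
  For fuzzy designs it runs once on the covariate-adjusted reduced-form
  outcome and the bandwidth is shared with the first stage, keeping the
  ITT/LATE identity exact; each outcome gets its own bandwidth.
- **Covariate adjustment.** The two-step scheme: unweighted OLS of the
  unadjusted outcome on the running-variable terms plus covariates within
  the bandwidth, then subtraction of the covariate part only. Because the
  adjustment equation carries no kernel weights, weighting enters only at
  the estimation stage. The chicken-and-egg between bandwidth and
  adjustment is resolved with one deterministic re-selection pass: pilot
  bandwidth on the unadjusted outcome → adjust → re-select on the
  adjusted outcome → re-adjust and estimate at the final bandwidth.
  Missing covariates are handled complete-case by default, with optional
  single mean/mode imputation (`missing="impute"`); multiple imputation
  is out of scope.
- **Weak instruments.** If the first-stage jump is below 0.01 the ratio
  estimate is suppressed (NaN) and the ITT is still reported.
- **Inference caveat.** Confidence intervals are conventional robust
  local-linear intervals, not "honest" fixed-smoothness intervals; with a
  discrete monthly running variable the default variance treats rows as
  independent. Simulation checks at the study conditions show two-sided
  type-I error of ~4-5% at α = 0.05 and CI coverage ≥ 92% for a planted
  0.15-SD complier effect.

## Preprocessing

- **Winsorization** uses Tukey fences with linear-interpolation quartiles
  (numpy's default rule — documented because the fences depend on it),
  applied once per outcome on the full sample before any bandwidth logic.
  Values beyond a fence are set exactly to it. With interpolated
  quartiles and a tiny heavy-tailed sample a capped extremum can re-enter
  the Q3 interpolation window, so exact idempotence is guaranteed when
  quartile positions are exact order statistics (n = 4k+1) or outliers
  are a minority — always the case at analysis scale; the property tests
  encode precisely that contract.
- **FDR** uses Benjamini–Hochberg step-up q-values (via statsmodels)
  within one modality at a time (m = regions in the panel), q = 0.05.

## Bayesian local randomization

- **Windows.** ω months on each side, adjacent to the cutoff: pre
  {−ω..−1}, post {0..ω−1}; defaults ω = 1 and ω = 5.
- **Model.** `outcome ~ assignment + covariates` with independent normal
  priors: focal coefficient `N(0, s·sd(y)/sd(x))` with s ∈ {0.5, 1, 1.5}
  (strong/medium/weak); nuisance coefficients autoscaled with multiplier
  2.5; intercept `N(ȳ, (2.5·sd(y))²)`; residual scale `σ ~
  Exponential(1/sd(y))`. The preregistration-style 2.5-SD focal prior is
  available but not a default (too wide for point-null testing).
- **Sampler.** Gibbs on the coefficient block (its exact conditional
  multivariate normal) with a random-walk Metropolis step on log σ; four
  chains, 80,000 total iterations by default for single fits, first half
  of each chain discarded as warmup. Split-rhat (arviz) must be < 1.05 or
  the fit raises. With σ fixed, the coefficient draws are exact
  independent draws from the conjugate posterior, which is the oracle
  contract the sampler is tested against (posterior mean/SD within 0.5%,
  Savage–Dickey BF within 3% at the default budget). An `analytic` method
  evaluates the conjugate posterior in closed form with a plug-in OLS σ —
  used for large replicate simulations where sampling every fit would add
  nothing but runtime; the pipeline default remains the sampler.
- **Savage–Dickey.** `BF01` is the marginal posterior density of the
  focal coefficient at 0 (normal approximation from the posterior
  moments; Gaussian KDE of the draws behind a flag) over the prior
  density at 0. BFs below 1 are reported as the multiplicative inverse,
  and grading uses Jeffreys' bands on the BF scale (1–3 anecdotal, 3–10
  moderate, 10–30 strong, 30–100 very strong, >100 extreme).
- **Covariate screening.** Before fitting, covariates are dropped (and
  logged) if they are deterministic functions of the running variable
  (the summer-born indicator at narrow windows), perfectly separated from
  assignment in-window (zero cell in the covariate × assignment table),
  or without in-window variance (site levels with no observations).
- **Association variant.** Identical machinery with continuous education
  years substituted for the assignment dummy, on the identical window;
  the estimand is an association, not a causal effect. Under the
  confounded scenario the ITT stays null-favoring while the association
  BF10 exceeds 3 in the large majority of replicates — the qualitative
  causal-vs-correlational divergence.

## Validity suite

- **Density (bunching) test:** exact two-sided binomial test of equal
  birth counts in equal-width windows (default ladder ω ∈ {1, 3, 6, 12}).
  This is a deliberate, assumption-light substitute for local-polynomial
  density tests, appropriate for a discrete monthly running variable; no
  attempt is made to reproduce any particular published density
  statistic. Calibration: rejection ~4.6% at window n = 1200 under
  uniform months; a 30% one-sided excess at that n is detected with
  power well above 80%.
- **Placebo outcomes** run the main estimators verbatim with each
  covariate as the outcome (no other covariates as adjusters), reported
  per variable without multiplicity correction; deterministic covariates
  are excluded with the reason.
- **Placebo cutoffs** re-centre the running variable at artificial
  cutoffs and re-run the sharp (ITT-style) estimator, with per-offset
  error entries when a shifted cutoff sits too close to the data edge.

## Pipeline

Order of operations is fixed: winsorize → adjust → bandwidth → estimate
(continuity) and winsorize → window → model (local randomization).
Continuity results are reported in raw outcome units per year of
education (LATE) and per assignment (ITT). Every output table derives
from a `RunConfig` whose hash and seed are written to the run manifest;
identical configuration and seed reproduce byte-identical TSVs. Errors
are isolated per outcome/region/window cell so one failing column never
aborts a run.

Problem sizes used by the test suite and the acceptance script (chosen as
a sensible simulation budget): 1000 null replicates for frequentist
calibration at 20 participants/month; 500 replicates at 200/month for
bias and coverage; 500-replicate brute-force bandwidth grids; 200
replicates for the window Bayes-factor behavior and the divergence
scenario at the study's 5-month window size (n ≈ 1200); the full default
pipeline once. The pipeline's default sampler budget is 20,000 total
iterations (the single-fit default stays at 80,000).

## Known limitations

- Conventional (not "honest") CIs; no bias-corrected higher-order local
  polynomials; single cutoff, no kink designs.
- The analytic Bayes path conditions on a plug-in residual scale; at
  window sizes in the hundreds-plus the difference from the sampled
  posterior is negligible (tested), but it would understate uncertainty
  in very small windows.
- MCAR missingness and complete-case analysis only; multiple imputation
  is intentionally out of scope.
- The generator's covariates are mutually independent; precision gains
  from adjustment are therefore conservative relative to real data with
  correlated nuisance structure.
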