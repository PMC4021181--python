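# Methods

## The estimation problem

`socwage` assigns each survey respondent a synthetic weekly wage from
three variables that almost every survey records: age, sex and an
occupation code from a tiered classification (SOC/ISCO-style digit
strings, 1-digit major groups refining down to 4-digit unit groups).
The estimate is intended as a continuous socio-economic covariate for
health models in datasets where income is absent or unreliable.  Only
the minor (3-digit) and unit (4-digit) tiers carry model terms; the
coarser tiers are represented in the code type but add no information
beyond the prefix structure.

## Master-data preparation

Raw wage records pass through a fixed stage order, with per-stage drop
counts retained: complete-case restriction on wage, age, sex and
occupation (unparseable codes and non-positive wages count as missing);
the working-age filter, 16–65 for men and 16–60 for women with both
bounds inclusive (occupation is uninformative about pension-age
income); an employment filter (people out of work carry no occupation
code; a missing flag counts as not employed); CPI deflation of wages to
reference-year prices, `wage × index(ref)/index(year)` with annual
indices (sub-annual price variation ignored); outlier trimming; and the
log transform.

The outlier rule is deliberately algorithmic where manual judgement is
often used.  Stage one drops wages outside the [0.1%, 99.9%] empirical
quantiles (linear-interpolation quantiles, so tiny samples can lose
their extreme order statistics — use an inclusive band for toy data).
Stage two checks the sample skewness (standard third-moment estimator)
of the retained log wages against a threshold of 1.0 and, while it is
exceeded, removes the value farthest from the median log wage
(median recomputed after each removal), capped at 1% of the rows that
survived stage one.  All three knobs are configurable; the defaults are
a reproducible stand-in for a judgement call, not an empirical claim.
Fewer than 10 surviving wages is treated as a degenerate distribution.
Note that on a clean log-normal population the quantile stage is pure
tail truncation and slightly attenuates covariate effects (about −2% on
the sex effect in our simulations); the estimator-recovery tests
therefore disable it, and analysts working with data known to be free
of gross errors may want to as well.

## Model family and fitting

For person *j* in unit group *k* nested in minor group *i*:

    log w_ijk = β0 + β_age·age + β_male·[male] + u_i + v_ik + (a_i + b_ik)·age + ε

with independent normal random effects (diagonal covariance — no
intercept–slope correlation term, as none is identified as necessary)
and configurations M1–M4 switching the minor-slope and unit terms on
and off.  Age enters uncentred by default, so the intercept is the
expected log wage of a woman at age 0 (≈5 log-£, ≈£165/week, on the
default generator scale); a centering constant is available purely for
numerical conditioning and is stored with the model so predictions are
invariant to it.

Estimation is maximum likelihood (REML behind a flag for sensitivity
analysis).  Observations in different minor groups are independent, so
every quantity is computed blockwise and exactly: per minor block the
Woodbury identity reduces the covariance `σ²I + ZGZ'` to the q×q system
`A = Z'Z + σ²G⁻¹` (q = 2 + 2·units in the block at most), and the
block's contribution to the likelihood, the GLS normal equations and
the BLUP solve all come from cross-products accumulated once.  Fixed
effects are profiled out by GLS at every variance-component candidate,
leaving at most a 5-dimensional search over log standard deviations
(positivity by construction).  The search is Nelder–Mead with a
convergence tolerance of 1e-8 on the log-likelihood, restarted once
from the incumbent optimum; the accepted-iterate likelihoods are
recorded and tested to be non-decreasing.  Variance estimates below
1e-10 are reported as exactly 0 with a boundary flag, and the final
likelihood and EB residuals are recomputed at the zeroed values so the
reported numbers are mutually consistent.  A singular within-block
system raises rather than returning a silently wrong likelihood.

The Empirical Bayes shrunk residual of a group is the posterior mean of
its random effect given the data and the (estimated) parameters,
`u = A⁻¹ Z'(y − Xβ)` per block.  For a single random intercept this is
the classical `(nτ²/(nτ² + σ²))·r̄`: groups with little data are pulled
toward zero, which is what makes the transfer usable for rare
occupations.  Correctness is established against independent dense
oracles (full multivariate-normal density; dense GLS BLUP solve) to
1e-6 / 1e-8 on small instances, and against statsmodels MixedLM as an
external reference for the two-level configuration.

## Transfer

Prediction assembles the fixed part from the target respondent's age and
sex and adds the EB residuals of their occupation groups.  Codes map
through the prefix hierarchy; an unseen unit group contributes zero unit
terms (fallback tier "minor"), an unseen or unresolvable minor group
drops all random terms (fallback tier "fixed-only").  This is the EB
answer — no data about a group means the prior mean — and keeps transfer
total.  The pound-scale estimate is the plain exponential by default,
which is the geometric-mean-consistent choice matching the geometric-mean
baselines of the internal validation; the log-normal smearing factor
`exp(σ²/2)` is available behind a flag for users who need arithmetic-mean
calibration.  Predictions are at reference-year prices by construction
and are not re-inflated.

## Validation

Internal: wages of a held-out survey year are predicted by each model
and by two baselines — the grand geometric mean of the training wages
and the per-unit-group geometric means (grand-mean fallback for unseen
groups).  The deviation metric is the standard deviation (n−1) of the
pound-scale residuals; a root-mean-square option exists because an SD is
blind to constant bias.  The headline "% reduction of deviation" is
computed on the variance scale, `100·(1 − (dev/dev₀)²)`; e.g. deviations
of £150 against a £209 baseline give 48.5%.

External: logistic regressions of a binary poor-health indicator
(worse-half response categories coded 1; the coding threshold is the
caller's choice since health-question scales differ between surveys) on
an income measure, adjusted for age and sex plus optional categorical
covariates, each model on its own complete cases.  Continuous fits scale
income in units of £100; decile fits use rank-based balanced deciles
(stable-order tie-breaking, lowest decile as reference, 9 indicators).
Estimation is Newton ML via statsmodels with Wald 95% intervals,
`OR = exp(β)`, `CI = exp(β ± 1.96·SE)`, and no small-sample or
multiple-testing corrections; perfect separation and rank deficiency
raise errors.  Model fit is compared across (possibly non-nested)
models by the correlation measure: the Pearson correlation between the
observed 0/1 outcomes and the fitted probabilities.

## Synthetic data

The generator draws a classification (3-digit minors sampled without
replacement, 3–5 unit digits each), group effects, and people with
sex-specific uniform working ages, then builds log wages from the M4
process above.  Defaults: 80 minor groups, 50,000 master records,
β0 = 5.1, β_age = 0.005, β_male = 0.27, intercept SDs √0.14 (minor) and
√0.10 (unit), unit age-slope SD √3e-5, no minor-slope variation,
residual SD √0.28 — magnitudes chosen to put wages on a realistic
£/week scale for a national labour-force survey.  Wages are inflated to
survey-year prices (2.5%/year around a 2006 reference) so preprocessing
has real deflation work; 3% of records are unemployed and 2% have
missing wages.  The health survey shares the same group effects
(drawn from a dedicated seed stream keyed only by config and
classification), reports income as the true wage times log-normal
transitory noise (SD 0.25 on the log scale — single-time-point income
mismeasures the medium-term average), and draws poor health from a
logit linear in true wage per £100 (slope −0.4, i.e. OR ≈ 0.67), age
(+0.02/year) and sex (−0.1 for men), giving ~25–30% prevalence.  A
5-level categorical covariate binned from the minor-group effect is a
synthetic stand-in for social-class/deprivation adjustment variables.
All generators are pure functions of the config; one seed feeds named
substreams so adding a stage never perturbs earlier draws.

What the generator does not emulate: real occupational wage
distributions (no calibration to actual survey tables), household
structure and income pooling, survey design weights, question-wording
effects on health reporting, and non-random missingness.  Passing tests
therefore demonstrate that the machinery is correct under the model's
own assumptions, not that the assumptions hold in any particular survey.

## Problem sizes and numerical choices

The heavy tests fit M4 on 50,000-row populations (ten replicates for
parameter recovery) and run 200 small-sample coverage replicates for
the Wald intervals; the full suite completes in a few minutes on one
CPU.  Recovery is judged on the mean across replicates: fixed effects
within ±2 Monte-Carlo standard errors, nonzero variance components
within ±15% relative error, and the truly-zero minor-slope variance at
the boundary.  Likelihood agreement with the dense oracle is asserted
to 1e-6 and BLUP agreement to 1e-8; model JSON serialisation is
lossless to full float precision; identical config and seed reproduce
every pipeline artifact byte-for-byte.

## Known limitations

Wages are estimated only for people in work; pension and welfare income
are out of scope, so retired and unemployed respondents get no
estimate.  No uncertainty intervals accompany individual predictions.
Crossed (non-nested) classifications, heteroscedastic residuals and
additional fixed covariates beyond age and sex are unsupported by
design — parsimony is what makes the transfer portable across surveys.
Mapping between classification revisions is a user concern.
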