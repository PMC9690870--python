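# Methods

## The compositional model

A respondent's day is treated as a 3-part composition of physical activity
(PA), sedentary behaviour (SB) and sleep (SL) in hours. Compositions carry
only relative information: rescaling a record by a positive constant changes
nothing the analysis uses. All log-ratio machinery (clr, ilr, variation
matrix, compositional mean) is therefore invariant to the closure constant;
we close to κ = 24 h for interpretability and keep the raw reported totals
separately, since typical survey records do not sum to exactly 24 h
(aggregated reported means sum to roughly 19.6 h). Plausibility filtering is
applied to the *raw* reported hours, before closure, because guideline-style
sleep ranges refer to actual clock time, not to the closure-inflated share.

The ilr basis is the pivot (sequential binary partition) basis: the first
coordinate contrasts one part against the geometric mean of the rest,
`z1 = sqrt(2/3) ln(x1 / sqrt(x2 x3))`, `z2 = sqrt(1/2) ln(x2/x3)`. The
canonical part order is (PA, SB, SL); all reported quantities are either
basis-invariant (predictions, R², model p, substitution deltas) or are
reported as the full set of three pivot rotations, which makes the part
order immaterial.

### Pivot coefficients and the sum-to-zero constraint

The regression of QoL on (z1, z2, age, sex) is fit by OLS (statsmodels
behind the `fit_ols` surface). For each behaviour p the "effect of p
relative to the others" is the z1 coefficient of the refit with p pivoted
first. Algebraically the three such coefficients are projections of a
single clr-scale gradient a (β_p = sqrt(3/2)·a_p, Σa_p = 0), so they must
sum to zero on any dataset; the package computes them both ways (refits and
projection) and the tests require agreement to 1e-9. `clr_gradient` warns
when handed a coefficient triple whose sum exceeds 0.05 in magnitude — such
a triple cannot have come from one fitted model. One of the published
yearly coefficient triples (3.06, 0.67, −2.39; sum 1.34) violates the
constraint; the package flags it rather than reproducing it, and the
four-wave simulation uses its sum-zero projection.

### Isotemporal substitution

Moving m hours from donor d to recipient r leaves the third part and the
total unchanged. Because the model is linear in log-ratios the predicted
change is Δ = Σ_p a_p (ln x'_p − ln x_p); covariates cancel exactly, Δ is
nonlinear in m, and d→r is not the mirror image of r→d. CIs use the
delta contrast (0, Δz1, Δz2, 0, 0): Var(Δ) = dᵀ Cov(coef) d with a t
quantile at the residual degrees of freedom (a normal quantile is available
by option; at n ≈ 1000 the difference is negligible). The default grid is
the 6 ordered pairs × {15, 30, 45, 60} minutes.

The baseline day for grid output is the sample's compositional (geometric)
mean closed to 24 h — the standard centre for compositional data. The
published table's baseline composition is not itself printed; re-evaluating
the published 2021 model at the published arithmetic-mean day (PA 3.83,
SB 4.59, SL 11.17 h, used as reported, i.e. closed to their own 19.59-h
total) reproduces all six printed 15-minute cells to within ±0.03 QoL
points, and the arithmetic baseline is available via `--baseline arithmetic`
in the CLI. The acceptance script uses the as-reported hours because that
is the only baseline the source tables pin down.

## PedsQL scoring

Raw 0–4 responses map to 100 − 25·raw. Dimension and total scores are
means over *answered* items; a score is missing only when no item of the
block was answered. A configurable ≥50%-completed rule (the common PedsQL
convention) exists but is off by default, matching the literal "divided by
the number of items completed" rule. The psychosocial score defaults to the
item mean over the emotional, social and school items (again the literal
reading); a dimension-mean variant is available. The toddler form (21
items) applies below the 5th birthday, the young-child form (23 items) from
age 5. Cronbach's alpha uses the classical k/(k−1)(1 − Σvar_i/var_total)
with unbiased variances and requires complete item matrices.

## Cleaning and imputation

Activity-to-behaviour mapping is configuration, with a default covering
chores/indoor/outdoor play (PA), screen and non-screen sitting activities
(SB), naps and night sleep (SL). The filter rejects records whose raw sleep
falls outside an age-banded plausibility range or whose behaviour total
exceeds 24 h. The library defaults to guideline sleep bands (11–14 h under
age 3, 10–13 h for 3+, naps included); the analysis scripts deliberately
pass a wider surrogate (9–16 h / 8–15 h), because guideline bands are
recommendations, not plausibility limits: applied as filters to data whose
reported sleep has sd ≈ 1.5 h they would discard ~40% of unremarkable
records, which no survey team would accept (the emulated study retained
88.7%). The exact criteria used by the original study are unpublished, so
this remains an explicit configuration choice.

Imputation is single-value: missing QoL gets the mean of the same
integer-age (floor) group, falling back to the overall mean for empty
groups; missing age gets the overall mean (the "same-age-group mean" rule is
circular for age itself); missing sex gets the mode, ties broken by first
occurrence. Imputation is idempotent and leaves observed cells untouched;
rates ≥5% per field trigger a warning but not failure.

## The synthetic-data generator

`generate_survey` emulates one survey wave:

- **Compositions.** ln(raw hours) is multivariate normal. Its centred
  projection G·C·G (G = I − 11ᵀ/3) equals the clr covariance
  Σ = −½·G·T·G implied by the target pairwise log-ratio variation matrix T,
  so closed compositions follow exactly the target logistic-normal; the free
  diagonal is set from per-part coefficients of variation so the *raw*
  marginal dispersions are realistic too (defaults: behaviour means
  (3.83, 4.59, 11.17) h, cv (0.59, 0.57, 0.135), T off-diagonals
  (0.50, 0.36, 0.41) — the scale of the emulated 2021 wave). An indefinite
  combination of T and cv is rejected at config time.
- **Outcome.** y = b0 + Σ a_p ln x_p + c_age·age + c_sex·sex + N(0, σ²)
  with Σa_p = 0 (default a: the published 2021 effect scale,
  (2.82, −2.61, −0.21)/√1.5). Because Σa = 0 the composition's overall
  scale cancels, so raw and closed hours give identical outcomes. σ
  defaults to the value that sets the model R² to a target (default 0.03,
  the emulated wave's explanatory power): σ² = s(1−R²)/R² where s is the
  systematic variance aᵀΣa + c_age²·Var(age) + c_sex²·Var(sex). Defaults
  c_age = 0.3 points/year and c_sex = −0.5 are deliberately weak nuisance
  effects (the source reports no covariate coefficients). Ages are uniform
  on [2, 6), sex Bernoulli(1/2). Outcome clipping to [0, 100] exists for
  display realism but is off by default because truncation biases OLS and
  the emulated analysis fit an untruncated linear model.
- **Plumbing.** Raw activity columns are fixed-share splits of each
  behaviour (they aggregate back exactly); optional PedsQL items are the
  target raw level plus grid-rounded noise (`item_noise_sd` tunes
  reliability empirically); missingness is injected independently per field
  at <5% defaults. All randomness flows from one `numpy` seed; identical
  configs give byte-identical tables, and a sidecar metadata dict records
  the seed and every true parameter for recovery tests.

What the generator does *not* emulate: year-on-year trend dynamics (a
multi-wave table is a loop over per-year configs), item-level factor
structure beyond a single reliability knob, survey weights, and any
dependence of missingness on observed values (missingness is MCAR). Tests
passing on these data therefore demonstrate correctness of the estimators
under the assumed model, not robustness to informative missingness or
reporting biases in real surveys.

## Numerical choices

- Unbiased (n−1) variances throughout; the variation matrix is computed
  from the log covariance in one pass and symmetrised.
- Compositional means sort column-wise before averaging logs so results are
  bit-identical under record permutation.
- Quantile grouping uses linear-interpolation sample quantiles; a score
  equal to a cut point joins the lower group (deterministic ties). k = 4
  groups by default.
- Zero durations are handled by multiplicative replacement with ε = 0.25 h
  (15 min — the reallocation granularity) before any log-ratio work;
  all-zero records are invalid.
- Rank-deficient designs raise rather than silently pseudo-inverting;
  constant outcomes report R² = 0.
- Model checking is a diagnostics report (residual skewness, excess
  kurtosis, Q–Q data), not a gate.
- Sex is coded girl = 0, boy = 1; coefficients are coding-invariant up to
  the intercept. Per-coefficient p-values are two-sided t tests.

## Problem sizes used in the checks

The verification suite runs Monte-Carlo studies sized for tight-but-fast
inference: 200 replicates of n = 1000 for coefficient recovery (mean
estimate within 2 Monte-Carlo SEs of truth), 500 replicates for 95% CI
coverage of the 15-minute SB→PA effect (observed coverage required in
[92.5%, 97.5%]), 1000 random datasets against the brute-force variation
matrix, and 1000 random compositions for transform round-trips. The
four-wave demonstration analysis uses the emulated study's own wave sizes
(2677/1961/2403/1004).

## Known limitations

- Only 3-part compositions are exercised; the pivot-basis code is written
  for general D but nothing above D = 3 is tested.
- Single imputation understates uncertainty; no multiple-imputation
  variance correction is attempted.
- The substitution model is first-order in log-ratios: no quadratic ilr
  terms, no three-way reallocations.
- The plausibility filter surrogate cannot recover the original study's
  exact record-exclusion decisions, which were never published.
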