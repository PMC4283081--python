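# Methods

## Model

Total GMS prescribing cost at a horizon year is a stratified product-sum over
the 160 region–gender–age (RGA) classes:

```
C = Σ_s  N_s · v_s · r_s · a_s
```

with `N_s` projected population, `v_s` medical-card coverage, `r_s` the
claims rate (fraction of card holders claiming in the year) and `a_s` the
average pharmacy cost per claimant (€/year). The model is purely stratified —
no regression on covariates; all heterogeneity lives in the 160-cell tables.

Uncertainty is propagated two ways:

1. **Scenario bracketing.** Each input table has minimum/mean/maximum
   variants. For estimated tables these are 95% confidence bounds
   (`point ± 1.96·SE`, clamped to the table's domain): binomial standard
   errors `√(p(1−p)/n)` for claims rates, `sample SD/√n` for costs. The
   normal quantile 1.96 is used rather than a t quantile because every
   stratum carries hundreds of observations. For coverage, where no sampling
   model applies, the historical national extremes (min/max of the 1996–2011
   series, as offsets from its mean) are applied uniformly across strata —
   a national shock model; per-stratum historical variation is not available.
2. **Monte Carlo ensemble.** Each of `n` iterations (default 100,000) samples
   a class by inverse-CDF lookup on the classes' cumulative empirical
   probabilities and perturbs its deterministic per-person cost
   `c_s = v_s r_s a_s` multiplicatively: `draw = c_s (1 + ε)`,
   `ε ~ N(0, 0.05)`. The noise is multiplicative because its dispersion is
   specified as a *fraction of cost* (5%), not an absolute euro amount.
   Draws that would be non-positive are rejected and redrawn; at 5% relative
   noise this is a ~20σ event and cannot bias results measurably. Since
   `E[1+ε] = 1`, the ensemble mean is unbiased for the closed-form
   expectation `Σ_s p_s c_s`, which is recorded alongside every result and
   used to verify convergence at rate `1/√n`.

Class sampling weights default to **eligible-person shares** (a draw is "a
person found in an RGA class" among those the scheme covers); a
population-share mode is provided because either reading of the sampling
frame is defensible. The two give different per-person means (eligible
weighting up-weights elderly, high-cost classes) but the same total cost,
which is computed deterministically.

## Coverage projection and the λ cap

Coverage is projected by anchoring each stratum's eligible-person count at
the base year (2011) and carrying it forward against the projected
population, optionally scaled by per-horizon eligibility growth multipliers.
Where the raw rate reaches 1.00 or above — possible in the oldest cohorts,
e.g. 105 projected eligible persons against a projected population of 100 —
an adjustment factor λ caps the rate: rates below 1.00 pass through
unchanged, rates ≥ 1.00 are replaced by λ (default 0.99, domain (0, 0.99]).
The hard clamp is the simplest rule satisfying the requirement that adjusted
coverage lie strictly below 1.00; it is a declared design choice (the
functional form of the adjustment is not otherwise constrained), and the
function is small and pluggable if a multiplicative rule is preferred.
Eligible persons are recomputed from the adjusted rate; they are kept
fractional internally and rounded half-up to whole persons only at reporting
time.

The claims rate is held at its base-2007 scenario values across all horizons:
the national claims rate has been stable above 90% for a decade and was
unaffected by the introduction of a small per-item co-payment.

Average cost per claim grows at a compound annual rate fitted to a national
historical series by the geometric mean, `(last/first)^(1/span) − 1`. On an
exact-compounding series this coincides with a log-linear regression fit and
it is parameter-free. The default synthetic history is back-cast from the
estimated 2007 national mean at **1.5%/year** with 1% multiplicative noise.
The choice is deliberately modest: historical GMS outlays grew much faster
(total medicines cost +15.2% over 2007–2011), but most of that growth was
coverage and volume, not cost per claimant, and post-2009 cost-containment
actually reduced cost per claimant; 1.5% represents a mild resumption of
cost growth. Projected totals scale roughly linearly in this rate, so users
studying price-led scenarios should set it explicitly.

## Synthetic data: what it emulates and what it does not

The generators stand in for three undeposited sources and are first-class,
tested code.

**Claims database** (`generate_claims_db`). Exactly
`records_per_cell_per_month × 160 × months` rows — 100 × 160 × 12 = 192,000
at the defaults. Per-record total cost is log-normal with the stratum's mean
from the packaged 2007 average-cost table and a relative dispersion
(`cost_cv`, default 0.30): drug costs are positive and strongly right-skewed,
and the log-normal is the standard minimal model with a fixed mean/CV. The
total is split deterministically in integer cents — ingredient ≈ 80%, VAT and
dispensing fee ≈ 10% each, residual cents to ingredient — so component
additivity is exact. Items per record are geometric (mean 2, ≥ 1) and forms
fixed at 1; these fields exist to complete the schema, not to model
dispensing behaviour. The real extract was a *systematic* sample (the first
100 records per cell per month); the generator draws i.i.d. records per cell,
which is the right null model for the estimators but cannot reproduce any
within-month ordering effects of the original extract.

**Population projections** (`generate_population`). A 2007 base of 4.3 m
persons is apportioned over cells by cohort, region and gender shares
(largest-remainder integer apportionment). Cohort shares are a one-time
realism choice calibrated so the 75+ cohort holds exactly 208,756 persons;
region shares start at the published 35.5% (Eastern) and 14.6% (Southern).
Each horizon's *growth increment* is then allocated across cells
proportionally to base size, a linear tilt of region shares toward their 2026
endpoints (Eastern 38.2%, Southern 13.6%) and seeded log-normal jitter
(sd 2%). Allocating the increment — rather than jittering levels and
rescaling — makes the headline aggregates exact by construction (grand total
= `round(base × growth)`, pinned cohorts exact, identity when all multipliers
are 1) while still giving heterogeneous cell trajectories. Default overall
growth multipliers are 1.068 (2011), 1.163 (2016), 1.247 (2021) and 1.326
(2026, the published +32.6%); the elderly cohorts follow a geometric path to
their published 2026 endpoints (70–74 ×1.854; 75+ ×422,589/208,756). The
generator makes no attempt to reproduce true county-level Irish demography —
only the printed national aggregates are calibrated, so regional results are
structurally plausible, not historical.

**Coverage history** (`generate_coverage_history`). Sixteen annual national
rates, 1996–2011, *constructed* so that the series minimum, mean and maximum
equal a configured triple exactly (default 0.28 / 0.31 / 0.369) and anchored
years take their published values (30.1% in 2007, 36.9% in 2011): extremes
are pinned at seeded positions, remaining years drawn uniformly and then
affinely squeezed toward the feasible bound to hit the mean. The default
minimum and mean are a one-time realism choice (the published record gives
only the two anchors); the maximum is the 2011 anchor.

**Base coverage tables.** Stratified 2007/2011 coverage is synthesised from a
cohort propensity profile (near-universal for 70+, reflecting the over-70s
entitlement; means-tested and lower at working ages) scaled so the national
rate is exact. Region and gender variation in coverage is not modelled —
regional cost variation enters through the claims-rate and average-cost
tables instead.

Consequently, passing tests demonstrate that the *method* — estimation,
scenario construction, projection, simulation, reporting — behaves correctly
on data with the assumed statistical structure; they do not validate the
published euro projections, which would require the original PCRS extract
and CSO regional projections.

## Estimators

- Claims rate: claimants / eligible per stratum; marginals are pooled ratios
  (Σ claimants / Σ eligible), matching the published national 96% from
  1,225,131 / 1,276,178.
- Average cost per claim: stratum total cost / claimant count (falling back
  to the per-record mean when claimant counts are not supplied; the generator
  emits one record per claimant-month, so per-record means estimate the same
  quantity). Grand total = overall cost / overall claimants.
- A stratum with no claims or with claimants exceeding eligible persons is a
  hard error naming the stratum — these indicate corrupted input, not valid
  states.

## Numerical and formatting choices

- Quantiles use linear interpolation between order statistics, numpy method
  `"weibull"` (type 6, the Minitab convention); the method is an argument of
  `describe` for users preferring type 7.
- Standard deviations use the n−1 denominator; `SE(mean) = SD/√n`.
- Integer apportionment is largest-remainder with a stable tie order, so
  cohort and grand totals are exact.
- RNG: numpy PCG64. One root seed; every generator draws from its own child
  stream (`SeedSequence(seed, spawn_key=(k,))` with fixed `k`), and the
  simulator separates uniform (class-sampling) and normal (error) streams, so
  sample paths are stable when components are added.
- Internal computation is at full float precision; reporting rounds to 2
  decimal places for rates and euro amounts and 1 for percentages. Currency
  in CSV is plain decimal, no locale separators.
- Marginal-consistency checks compare printed table totals against
  weight-recomputed values at a 0.5% relative tolerance (printed totals are
  claimant-weighted with unpublished weights); the check is report-only.

## Problem sizes

The default study uses the full published geometry throughout: the 192,000-row
claims database, all 160 strata, and 100,000 Monte Carlo iterations per
scenario × horizon cell (nine cells). A complete build-and-simulate run takes
a few seconds on one CPU, so no scaled-down mode is needed.

## Limitations

- The 10-cohort age scheme is fixed (a closed enumeration); the finer
  12-cohort variant splitting the over-80s is not supported.
- Coverage scenarios apply national offsets uniformly across strata;
  per-stratum historical coverage variation is not modelled.
- No policy-response modelling: income-limit changes, GP-visit cards and
  co-payment demand effects are out of scope (the claims rate is held fixed
  on the evidence that the small co-payment did not move it).
- No variance reduction in the Monte Carlo engine (plain sampling only), and
  no significance testing of the main effects — the decomposition ranks
  factors by the range of level means, which recombine exactly to the grand
  mean under draw-count weighting.
- Printed row totals in the packaged tables are transcriptions; one
  (North-Western female, 716.16) cannot be reproduced from its row under any
  uniform weighting and is carried as printed.
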