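# gms-costsim

Stratified Monte Carlo projection of Irish **General Medical Services (GMS)**
prescribing costs to 2016, 2021 and 2026.

The GMS scheme entitles Irish medical-card holders to free prescription drugs.
Its total cost is driven by four quantities, each stratified over the 160
region–gender–age classes (8 former health-board regions × 2 genders × 10 age
cohorts, an *RGA class*):

```
total cost = Σ_s  population_s × coverage_s × claims_rate_s × avg_cost_s
```

where, for stratum *s*, *coverage* is the fraction of the population holding a
medical card, *claims rate* the fraction of card holders who claim in the
year, and *avg cost* the average pharmacy cost per claimant (€). Uncertainty
is propagated by a plain Monte Carlo ensemble: each of 100,000 iterations
samples an RGA class by inverse-CDF lookup on the classes' cumulative
empirical probabilities (eligible-person shares) and draws a per-person cost

```
draw = coverage_s × claims_rate_s × avg_cost_s × (1 + ε),   ε ~ N(0, 0.05)
```

so the Gaussian error's standard deviation is 5% of cost. Scenario analysis
brackets every input table with minimum/mean/maximum variants built from 95%
confidence intervals (or historical extremes for coverage), and coverage
rates that demographic decline pushes to 1.00 or above are capped strictly
below 1.00 by an adjustment factor λ ∈ (0, 0.99].

Because the underlying claims extract (PCRS) and the official regional
population projections (CSO) are not publicly deposited, the package ships a
first-class synthetic-data layer that emulates them: a 192,000-row claims
database (100 records per RGA class per month), stratified population tables
whose headline aggregates (4.3 m persons in 2007 growing 32.6% by 2026; the
75+ cohort doubling from 208,756 to 422,589) hold exactly by construction,
and a national coverage history for 1996–2011 anchored at the published
30.1% (2007) and 36.9% (2011). The two published 2007 input tables — the
mean-scenario claims rate and average cost per claim by region, gender and
cohort — are packaged as transcribed CSV fixtures.

Intended users: health economists and analysts projecting demand-driven
pharmaceutical expenditure under demographic change, and anyone needing a
tested, seeded implementation of stratified categorical Monte Carlo cost
simulation.

## Worked example

```python
import gms_costsim as g

study = g.build_study(seed=42)                       # generate + estimate + project
results, totals = g.run_simulations(study, n_iterations=100_000)

row = g.describe(results[(2, 2016)].costs)           # scenario 2 = mean, 2016
print(f"2016 mean scenario: mean €{row.mean:.2f}, SD €{row.st_dev:.2f}, "
      f"median €{row.median:.2f}")
for h in (2016, 2021, 2026):
    print(f"{h}: total GMS cost €{totals[(2, h)]/1e9:.2f} bn "
          f"(min €{totals[(1, h)]/1e9:.2f} bn, max €{totals[(3, h)]/1e9:.2f} bn)")
effects = g.main_effects(results[(2, 2016)])
print("dominant cost driver:", effects.factor_ranking[0])
```

prints

```
2016 mean scenario: mean €470.20, SD €459.03, median €217.66
2016: total GMS cost €1.61 bn (min €1.46 bn, max €1.85 bn)
2021: total GMS cost €2.01 bn (min €1.83 bn, max €2.32 bn)
2026: total GMS cost €2.29 bn (min €2.08 bn, max €2.64 bn)
dominant cost driver: cohort
```

The per-draw mean (€470) is the expected annual pharmacy cost per *eligible*
person — the simulator weights classes by eligible-person shares, which
up-weights the elderly, high-cost classes; the totals multiply the full
per-person deterministic cost into the projected population. Total cost rises
with each horizon (population growth plus coverage growth plus cost growth),
the three scenario totals are ordered minimum ≤ mean ≤ maximum, and age
cohort dominates gender and region as a cost driver, with the 70+ and 0–11
cohorts carrying the largest demographic momentum.

The same steps are available from a shell:

```bash
gms-costsim --seed 42 --out-dir out generate      # synthetic claims DB + populations
gms-costsim --seed 42 --out-dir out estimate      # rate tables + 95%-CI scenarios
gms-costsim --seed 42 --out-dir out project       # coverage/cost to 2016/2021/2026
gms-costsim --seed 42 --out-dir out simulate --horizon 2016 --scenario 2
gms-costsim --seed 42 --out-dir out report        # full scenario × horizon table
```

All outputs are CSV/JSON with a one-line provenance header (fixture hash,
seed, config hash); every stochastic step is reproducible from the root seed.

## Layout

- `src/gms_costsim/strata.py` — region/gender/cohort vocabulary, rate and
  population tables, fixture I/O, marginal-consistency checks
- `src/gms_costsim/synthetic_data.py` — claims-database, population and
  coverage-history generators
- `src/gms_costsim/estimation.py` — claims-rate / average-cost estimators,
  95%-CI scenario sets
- `src/gms_costsim/projection.py` — coverage capping (λ), coverage and
  average-cost projection, historical growth fitting
- `src/gms_costsim/mc_engine.py` — class distribution, inverse-CDF sampling,
  the simulation ensemble, total cost
- `src/gms_costsim/reporting.py` — descriptive statistics, main effects,
  scenario tables, histogram tables
- `src/gms_costsim/pipeline.py` — end-to-end study assembly
- `src/gms_costsim/data/` — transcribed 2007 claims-rate and average-cost
  fixtures
- `docs/methods.md` — model assumptions, parameter defaults and limitations
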