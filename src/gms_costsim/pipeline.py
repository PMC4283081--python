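"""End-to-end assembly of the default study.

Chains the synthetic generators, estimators, projections and simulator into
one seeded, reproducible run: generate the claims database and population
projections, estimate claims-rate and average-cost tables with their 95%-CI
scenarios, build coverage scenarios from the historical series, project
coverage and cost to 2016/2021/2026, and simulate each scenario x horizon
cell.  National aggregates are calibrated to the published figures (4.3 m
population in 2007 growing 32.6% by 2026, coverage 30.1% in 2007 and 36.9% in
2011, projected national coverage ~34.7/37.5/37.2% at the three horizons).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    ScenarioSet,
    avg_cost_scenarios,
    claims_rate_scenarios,
    estimate_avg_cost,
    estimate_claims_rate,
)
from .mc_engine import SimulationResult, SimulationSpec, simulate, total_cost
from .projection import (
    DEFAULT_LAMBDA,
    CoverageProjection,
    GrowthModel,
    extrapolate_avg_cost,
    fit_historical_growth,
    project_coverage,
)
from .strata import (
    Cohort,
    PopulationTable,
    RateTable,
    StratumKey,
    all_strata,
)
from .synthetic_data import (
    SyntheticConfig,
    generate_claims_db,
    generate_coverage_history,
    generate_population,
    sample_claimants,
)

__all__ = [
    "Study",
    "build_study",
    "run_simulations",
    "synthetic_base_coverage",
    "synthetic_cost_history",
    "DEFAULT_HORIZONS",
    "NATIONAL_COVERAGE_TARGETS",
]

DEFAULT_HORIZONS = (2016, 2021, 2026)

#: published projected national coverage rates used as calibration inputs
NATIONAL_COVERAGE_TARGETS = {2016: 0.347, 2021: 0.375, 2026: 0.372}

#: relative cohort propensity to hold a medical card (elderly near-universal
#: under the over-70s entitlement; working ages means-tested and lower)
_COVERAGE_PROFILE: dict[Cohort, float] = {
    Cohort.C0_11: 0.36,
    Cohort.C12_15: 0.34,
    Cohort.C16_24: 0.30,
    Cohort.C25_34: 0.25,
    Cohort.C35_44: 0.26,
    Cohort.C45_54: 0.30,
    Cohort.C55_64: 0.36,
    Cohort.C65_69: 0.55,
    Cohort.C70_74: 0.96,
    Cohort.C75_PLUS: 0.97,
}
_PINNED_COHORTS = (Cohort.C70_74, Cohort.C75_PLUS)

#: default compound annual growth of average cost per claim used to build the
#: synthetic historical series (see docs/methods.md for the rationale)
DEFAULT_COST_GROWTH = 0.015


def synthetic_base_coverage(population: PopulationTable, national_rate: float) -> RateTable:
    """A stratified coverage table hitting a national rate exactly.

    Elderly cohorts keep their near-universal profile values; the remaining
    cohorts' profile values are scaled by one common factor so that eligible
    persons sum to ``national_rate x total population``.
    """
    if not 0.0 < national_rate < 1.0:
        raise ValueError("national_rate must be in (0, 1)")
    pinned_elig = sum(_COVERAGE_PROFILE[k.cohort] * population[k]
                      for k in all_strata() if k.cohort in _PINNED_COHORTS)
    free_elig = sum(_COVERAGE_PROFILE[k.cohort] * population[k]
                    for k in all_strata() if k.cohort not in _PINNED_COHORTS)
    target = national_rate * population.total()
    scale = (target - pinned_elig) / free_elig
    if scale <= 0:
        raise ValueError("national rate unattainably low given elderly entitlement")
    values = {}
    for k in all_strata():
        v = _COVERAGE_PROFILE[k.cohort] * (1.0 if k.cohort in _PINNED_COHORTS else scale)
        values[k] = min(v, 0.99)
    return RateTable("coverage", values)


def synthetic_cost_history(
    config: SyntheticConfig,
    base_value: float,
    annual_growth: float = DEFAULT_COST_GROWTH,
    noise_sd: float = 0.01,
    years: tuple[int, int] = (1996, 2007),
) -> pd.Series:
    """National average-cost-per-claim series ending exactly at ``base_value``.

    Back-cast from the anchor year at ``annual_growth`` compound, with seeded
    log-normal noise (sd ``noise_sd``) on the non-anchor years.
    """
    first, last = years
    rng = config.rng(4)  # dedicated child stream
    idx = list(range(first, last + 1))
    vals = []
    for y in idx:
        v = base_value / (1.0 + annual_growth) ** (last - y)
        if y != last and noise_sd > 0:
            v *= float(rng.lognormal(0.0, noise_sd))
        vals.append(v)
    return pd.Series(vals, index=pd.Index(idx, name="year"), name="avg_cost")


def _coverage_offset_scenarios(base: RateTable, history: pd.Series) -> ScenarioSet:
    """Min/mean/max coverage from historical national extremes.

    The national offsets (historical min - mean, max - mean) are applied
    uniformly across strata and clamped to [0, 1].
    """
    hist_mean = float(history.mean())
    lo_off = float(history.min()) - hist_mean
    hi_off = float(history.max()) - hist_mean
    clamp = lambda v: min(max(v, 0.0), 1.0)
    return ScenarioSet(
        minimum=base.map_values(lambda v: clamp(v + lo_off)),
        mean=base,
        maximum=base.map_values(lambda v: clamp(v + hi_off)),
        method="historical_extremes",
    )


@dataclass
class Study:
    """All inputs and intermediate tables of one seeded study run."""

    config: SyntheticConfig
    populations: dict[int, PopulationTable]
    coverage_history: pd.Series
    cost_history: pd.Series
    claims_db: pd.DataFrame
    eligible_2007: dict[StratumKey, int]
    claimants_2007: dict[StratumKey, int]
    claims_rate: ScenarioSet
    avg_cost: ScenarioSet
    base_coverage_2011: RateTable
    coverage_scenarios: ScenarioSet
    annual_cost_growth: float
    eligible_growth: dict[int, float]
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    lam: float = DEFAULT_LAMBDA
    coverage_projections: dict[tuple[int, int], CoverageProjection] = field(default_factory=dict)

    def coverage_at(self, scenario: int, horizon: int) -> CoverageProjection:
        return self.coverage_projections[(scenario, horizon)]

    def avg_cost_at(self, scenario: int, horizon: int) -> RateTable:
        model = GrowthModel(base=self.avg_cost[scenario],
                            annual_growth=self.annual_cost_growth, anchor_year=2007)
        return extrapolate_avg_cost(model, horizon)


def build_study(
    seed: int,
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    lam: float = DEFAULT_LAMBDA,
    config: SyntheticConfig | None = None,
) -> Study:
    """Generate inputs, estimate tables and project all scenarios/horizons."""
    config = config if config is not None else SyntheticConfig(seed=seed)
    populations = generate_population(config)
    coverage_history = generate_coverage_history(config)
    claims_db = generate_claims_db(config)

    # 2007 claims-rate estimation from eligible persons and sampled claimants
    base_cov_2007 = synthetic_base_coverage(populations[2007],
                                            config.coverage_anchors.get(2007, 0.301))
    eligible_2007 = {k: int(round(base_cov_2007[k] * populations[2007][k]))
                     for k in all_strata()}
    claimants_2007 = sample_claimants(eligible_2007, config.resolved_claim_probability(),
                                      config)
    rate_point = estimate_claims_rate(claimants_2007, eligible_2007)
    claims_rate = claims_rate_scenarios(rate_point, eligible_2007)

    # 2007 average cost per claim from the synthetic claims database
    cost_point = estimate_avg_cost(claims_db)
    avg_cost = avg_cost_scenarios(cost_point, claims_db)

    # historical cost growth, back-cast from the estimated national mean
    cost_history = synthetic_cost_history(config, base_value=cost_point.grand_total
                                          or float(np.mean(list(cost_point.values.values()))))
    growth = fit_historical_growth(cost_history)

    # 2011 coverage base and historical-extreme scenarios
    base_cov_2011 = synthetic_base_coverage(populations[2011],
                                            config.coverage_anchors.get(2011, 0.369))
    coverage_scenarios = _coverage_offset_scenarios(base_cov_2011, coverage_history)

    # eligible-person trajectory calibrated to the published national rates
    anchor_total = sum(base_cov_2011[k] * populations[2011][k] for k in all_strata())
    eligible_growth = {
        h: NATIONAL_COVERAGE_TARGETS.get(h, 1.0) * populations[h].total() / anchor_total
        for h in horizons
    }

    study = Study(
        config=config,
        populations=populations,
        coverage_history=coverage_history,
        cost_history=cost_history,
        claims_db=claims_db,
        eligible_2007=eligible_2007,
        claimants_2007=claimants_2007,
        claims_rate=claims_rate,
        avg_cost=avg_cost,
        base_coverage_2011=base_cov_2011,
        coverage_scenarios=coverage_scenarios,
        annual_cost_growth=growth,
        eligible_growth=eligible_growth,
        horizons=tuple(horizons),
        lam=lam,
    )
    for scenario in (1, 2, 3):
        proj = project_coverage(
            coverage_scenarios[scenario], populations[2011],
            {h: populations[h] for h in horizons},
            lam=lam, eligible_growth=eligible_growth,
        )
        for h in horizons:
            study.coverage_projections[(scenario, h)] = proj[h]
    return study


def _sim_seed(root_seed: int, horizon: int) -> int:
    # shared across scenarios at a horizon so scenario comparisons are coupled
    return int(np.random.SeedSequence(root_seed, spawn_key=(5, horizon))
               .generate_state(1)[0] % (2 ** 31))


def run_simulations(
    study: Study,
    n_iterations: int = 100_000,
    scenarios: tuple[int, ...] = (1, 2, 3),
    noise_sd_fraction: float = 0.05,
    weight_mode: str = "eligible",
) -> tuple[dict[tuple[int, int], SimulationResult], dict[tuple[int, int], float]]:
    """Simulate every scenario x horizon cell; returns (results, total costs in €).

    ``weight_mode`` picks the class-sampling weights: ``"eligible"`` (default)
    weights classes by eligible-person shares, ``"population"`` by total
    population shares.
    """
    if weight_mode not in ("eligible", "population"):
        raise ValueError("weight_mode must be 'eligible' or 'population'")
    results: dict[tuple[int, int], SimulationResult] = {}
    totals: dict[tuple[int, int], float] = {}
    root_seed = study.config.seed
    if root_seed is None:
        raise ValueError("study config must carry a seed")
    for scenario in scenarios:
        claims = study.claims_rate[scenario]
        for horizon in study.horizons:
            proj = study.coverage_at(scenario, horizon)
            cost = study.avg_cost_at(scenario, horizon)
            weights = (proj.eligible if weight_mode == "eligible"
                       else dict(study.populations[horizon].counts))
            spec = SimulationSpec(horizon=horizon, scenario=scenario,
                                  n_iterations=n_iterations,
                                  noise_sd_fraction=noise_sd_fraction,
                                  seed=_sim_seed(root_seed, horizon))
            results[(scenario, horizon)] = simulate(
                spec, weights, proj.coverage, claims, cost)
            totals[(scenario, horizon)] = total_cost(
                study.populations[horizon].counts, proj.coverage, claims, cost)
    return results, totals
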