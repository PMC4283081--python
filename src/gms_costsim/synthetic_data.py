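"""Synthetic stand-ins for the study's data sources.

The real analysis draws on three inputs that are not publicly deposited: a
sample of the PCRS (Primary Care Reimbursement Service) claims database, CSO
regional population projections, and a historical national medical-card
coverage series.  This module generates statistically structured substitutes
for all three so the downstream pipeline is fully testable offline:

* :func:`generate_claims_db` — a claims table with the published schema
  (month x region x gender x age cohort; ingredient cost, VAT, dispensing
  fee, total cost, items, forms), 100 records per cell per month = 192,000
  rows at the defaults, with per-stratum mean cost calibrated to the packaged
  2007 average-cost table.
* :func:`generate_population` — stratified population tables for the horizons
  2007/2011/2016/2021/2026 whose headline aggregates (overall growth, pinned
  elderly-cohort growth) are reproduced exactly by construction, with seeded
  cell-level heterogeneity in how growth is allocated.
* :func:`generate_coverage_history` — an annual national coverage series
  1996–2011 whose min/mean/max match a configured triple exactly and which
  honours per-year anchors (e.g. the published 30.1% for 2007).

All randomness flows from one root seed; each generator draws from its own
child stream (fixed ``spawn_key``) so adding a generator never perturbs the
outputs of an existing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .strata import (
    COHORTS,
    GENDERS,
    REGIONS,
    Cohort,
    Gender,
    PopulationTable,
    RateTable,
    Region,
    StratumKey,
    all_strata,
    load_fixture,
)

__all__ = [
    "ClaimRecord",
    "SyntheticConfig",
    "generate_claims_db",
    "generate_population",
    "generate_coverage_history",
    "sample_claimants",
    "iter_records",
]

HORIZONS = (2007, 2011, 2016, 2021, 2026)
COVERAGE_YEARS = tuple(range(1996, 2012))  # 16 annual values

# child-stream identifiers; fixed forever so sample paths are stable
_STREAM_CLAIMS = 0
_STREAM_POPULATION = 1
_STREAM_COVERAGE = 2
_STREAM_CLAIMANTS = 3

# Ireland 2007 baseline structure (national aggregates; shares are a one-time
# realism choice, see docs/methods.md).  The 75+ share pins the published
# 208,756-person baseline at the default 4.3 m total; the 35-44 share absorbs
# the residual so the shares sum to exactly 1.
_DEFAULT_COHORT_SHARES: dict[Cohort, float] = {
    Cohort.C0_11: 0.175,
    Cohort.C12_15: 0.050,
    Cohort.C16_24: 0.130,
    Cohort.C25_34: 0.170,
    Cohort.C45_54: 0.120,
    Cohort.C55_64: 0.095,
    Cohort.C65_69: 0.034,
    Cohort.C70_74: 0.0325,
    Cohort.C75_PLUS: 208_756 / 4_300_000,
}
_DEFAULT_COHORT_SHARES[Cohort.C35_44] = 1.0 - sum(_DEFAULT_COHORT_SHARES.values())

_DEFAULT_REGION_SHARES: dict[Region, float] = {
    Region.EASTERN: 0.355,
    Region.MIDLAND: 0.059,
    Region.MID_WESTERN: 0.085,
    Region.NORTH_EASTERN: 0.092,
    Region.NORTH_WESTERN: 0.055,
    Region.SOUTH_EASTERN: 0.109,
    Region.SOUTHERN: 0.146,
    Region.WESTERN: 0.099,
}

# published endpoints: Eastern 35.5% -> 38.2%, Southern 14.6% -> 13.6% by 2026
_REGION_SHARES_2026 = {Region.EASTERN: 0.382, Region.SOUTHERN: 0.136}

_OVER75_GROWTH_2026 = 422_589 / 208_756          # doubling of the 75+ cohort
_OVER70_74_GROWTH_2026 = 1.854                   # +85.4% for 70-74


def _default_overall_growth() -> dict[int, float]:
    # 2026 pinned to the published +32.6%; intermediates follow the published
    # 2011 coverage denominator (1,694,063 / 0.369 ~ 4.59 m) and a smooth path.
    return {2007: 1.0, 2011: 1.068, 2016: 1.163, 2021: 1.247, 2026: 1.326}


def _default_cohort_growth() -> dict[int, dict[Cohort, float]]:
    """Elderly-cohort multipliers, geometric path to the published 2026 endpoints."""
    out: dict[int, dict[Cohort, float]] = {}
    for year in HORIZONS:
        frac = (year - 2007) / (2026 - 2007)
        out[year] = {
            Cohort.C70_74: _OVER70_74_GROWTH_2026 ** frac,
            Cohort.C75_PLUS: _OVER75_GROWTH_2026 ** frac,
        }
    return out


@dataclass(frozen=True)
class ClaimRecord:
    """One synthetic PCRS claim row.

    ``total_cost`` equals ``ingredient_cost + vat + dispensing_fee`` exactly
    to the cent, and ``n_items >= n_forms``.
    """

    month: int
    stratum: StratumKey
    ingredient_cost: float
    vat: float
    dispensing_fee: float
    total_cost: float
    n_items: int
    n_forms: int


@dataclass
class SyntheticConfig:
    """Configuration for all three generators.

    Defaults reproduce the study conditions: 100 records per region–gender–
    cohort cell per month (192,000 rows), per-stratum mean costs from the
    packaged 2007 average-cost table, claim probabilities from the packaged
    2007 claims-rate table, a 4.3 m 2007 population growing 32.6% by 2026,
    and a coverage history anchored at 30.1% (2007) and 36.9% (2011).
    """

    seed: int | None = None
    records_per_cell_per_month: int = 100
    months: Sequence[int] = tuple(range(1, 13))
    cost_means: RateTable | None = None          # default: packaged avg_cost_2007
    cost_cv: float = 0.30
    claim_probability: RateTable | None = None   # default: packaged claims_rate_2007
    population_2007_total: int = 4_300_000
    overall_growth: dict[int, float] = field(default_factory=_default_overall_growth)
    cohort_growth: dict[int, dict[Cohort, float]] = field(default_factory=_default_cohort_growth)
    cohort_shares: dict[Cohort, float] = field(default_factory=lambda: dict(_DEFAULT_COHORT_SHARES))
    region_shares: dict[Region, float] = field(default_factory=lambda: dict(_DEFAULT_REGION_SHARES))
    region_shares_2026: dict[Region, float] = field(default_factory=lambda: dict(_REGION_SHARES_2026))
    gender_share_male: float = 0.5
    population_jitter_sd: float = 0.02
    coverage_history_range: tuple[float, float, float] = (0.28, 0.31, 0.369)
    coverage_anchors: dict[int, float] = field(default_factory=lambda: {2007: 0.301, 2011: 0.369})

    def __post_init__(self) -> None:
        if self.records_per_cell_per_month <= 0:
            raise ValueError("records_per_cell_per_month must be a positive integer")
        if self.cost_cv < 0:
            raise ValueError("cost_cv must be >= 0")
        if not self.months or any(m not in range(1, 13) for m in self.months):
            raise ValueError("months must be a non-empty subset of 1..12")
        if self.population_2007_total <= 0:
            raise ValueError("population_2007_total must be > 0")
        for year, g in self.overall_growth.items():
            if g <= 0:
                raise ValueError(f"overall growth multiplier for {year} must be > 0")
        for year, d in self.cohort_growth.items():
            for cohort, g in d.items():
                if g <= 0:
                    raise ValueError(f"cohort growth multiplier for {cohort} @{year} must be > 0")
        lo, mid, hi = self.coverage_history_range
        if not (0.0 <= lo <= mid <= hi <= 1.0):
            raise ValueError("coverage_history_range must satisfy 0 <= min <= mean <= max <= 1")
        if not 0.0 < self.gender_share_male < 1.0:
            raise ValueError("gender_share_male must be in (0, 1)")
        if self.population_jitter_sd < 0:
            raise ValueError("population_jitter_sd must be >= 0")

    # lazily resolved fixture defaults -------------------------------------
    def resolved_cost_means(self) -> RateTable:
        return self.cost_means if self.cost_means is not None else load_fixture("avg_cost_2007.csv")

    def resolved_claim_probability(self) -> RateTable:
        return (self.claim_probability if self.claim_probability is not None
                else load_fixture("claims_rate_2007.csv"))

    def rng(self, stream: int) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic generator call")
        return np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))))


# ---------------------------------------------------------------------------
# claims database
# ---------------------------------------------------------------------------

def generate_claims_db(config: SyntheticConfig) -> pd.DataFrame:
    """Generate the synthetic PCRS-like claims table.

    Exactly ``records_per_cell_per_month x 160 x len(months)`` rows.  Per-record
    total cost is log-normal with the stratum's configured mean and relative
    dispersion ``cost_cv`` (drug costs are positive and right-skewed); at
    ``cost_cv = 0`` every record equals the stratum mean.  The total is split
    deterministically into components — ingredient cost ~80%, VAT and
    dispensing fee ~10% each — in integer cents so additivity is exact.
    """
    means_table = config.resolved_cost_means()
    rng = config.rng(_STREAM_CLAIMS)
    rpc = config.records_per_cell_per_month
    months = list(config.months)
    strata = list(all_strata())
    n_cells = len(months) * len(strata)
    n = n_cells * rpc

    month_col = np.repeat(np.array(months, dtype=np.int64), len(strata) * rpc)
    stratum_idx = np.tile(np.repeat(np.arange(len(strata)), rpc), len(months))
    means = np.array([means_table[s] for s in strata])[stratum_idx]

    if config.cost_cv == 0:
        total = means.copy()
    else:
        # log-normal with E[X] = mean and SD/mean = cost_cv
        sigma2 = np.log1p(config.cost_cv ** 2)
        mu = np.log(means) - sigma2 / 2.0
        total = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))

    total_c = np.rint(total * 100).astype(np.int64)
    total_c = np.maximum(total_c, 1)  # a claim always has positive cost
    vat_c = total_c // 10
    fee_c = total_c // 10
    ing_c = total_c - vat_c - fee_c   # residual cent(s) land in ingredient cost

    n_items = rng.geometric(0.5, size=n).astype(np.int64)  # >= 1, mean 2
    n_forms = np.ones(n, dtype=np.int64)

    df = pd.DataFrame({
        "month": month_col,
        "region": pd.Categorical.from_codes(
            np.array([REGIONS.index(s.region) for s in strata])[stratum_idx],
            categories=[r.value for r in REGIONS]),
        "gender": pd.Categorical.from_codes(
            np.array([GENDERS.index(s.gender) for s in strata])[stratum_idx],
            categories=[g.value for g in GENDERS]),
        "cohort": pd.Categorical.from_codes(
            np.array([COHORTS.index(s.cohort) for s in strata])[stratum_idx],
            categories=[c.value for c in COHORTS]),
        "ingredient_cost": ing_c / 100.0,
        "vat": vat_c / 100.0,
        "dispensing_fee": fee_c / 100.0,
        "total_cost": total_c / 100.0,
        "n_items": n_items,
        "n_forms": n_forms,
    })
    return df


def iter_records(df: pd.DataFrame) -> Iterator[ClaimRecord]:
    """View a claims DataFrame as a stream of :class:`ClaimRecord` objects."""
    for row in df.itertuples(index=False):
        yield ClaimRecord(
            month=int(row.month),
            stratum=StratumKey(Region(row.region), Gender(row.gender), Cohort(row.cohort)),
            ingredient_cost=float(row.ingredient_cost),
            vat=float(row.vat),
            dispensing_fee=float(row.dispensing_fee),
            total_cost=float(row.total_cost),
            n_items=int(row.n_items),
            n_forms=int(row.n_forms),
        )


def sample_claimants(
    eligible: Mapping[StratumKey, int],
    claim_probability: RateTable,
    config: SyntheticConfig,
) -> dict[StratumKey, int]:
    """Draw per-stratum claimant counts ~ Binomial(eligible, claim probability)."""
    rng = config.rng(_STREAM_CLAIMANTS)
    out: dict[StratumKey, int] = {}
    for key in all_strata():
        n = int(eligible.get(key, 0))
        out[key] = int(rng.binomial(n, claim_probability[key])) if n > 0 else 0
    return out


# ---------------------------------------------------------------------------
# population projections
# ---------------------------------------------------------------------------

def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of an integer total over weights."""
    if total == 0:
        return np.zeros(len(weights), dtype=np.int64)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("apportionment weights must have positive sum")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(np.int64)
    residual = int(total - base.sum())
    if residual:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:residual]] += 1
    return base


def _region_factor(config: SyntheticConfig, year: int) -> dict[Region, float]:
    """Growth tilt pushing region shares linearly toward their 2026 targets."""
    frac = min(max((year - 2007) / (2026 - 2007), 0.0), 1.0)
    pinned = config.region_shares_2026
    base = config.region_shares
    pinned_base = sum(base[r] for r in pinned)
    pinned_target = sum(pinned.values())
    scale_rest = (1.0 - pinned_target) / (1.0 - pinned_base)
    out: dict[Region, float] = {}
    for r in REGIONS:
        target = pinned.get(r, base[r] * scale_rest)
        share = base[r] + frac * (target - base[r])
        out[r] = share / base[r]
    return out


def _base_population_2007(config: SyntheticConfig) -> dict[StratumKey, int]:
    total = config.population_2007_total
    cohort_shares = np.array([config.cohort_shares[c] for c in COHORTS], dtype=float)
    cohort_totals = _apportion(total, cohort_shares)
    counts: dict[StratumKey, int] = {}
    cell_w = np.array(
        [config.region_shares[r] * (config.gender_share_male if g is Gender.MALE
                                    else 1.0 - config.gender_share_male)
         for r in REGIONS for g in GENDERS], dtype=float)
    for ci, cohort in enumerate(COHORTS):
        cells = _apportion(int(cohort_totals[ci]), cell_w)
        i = 0
        for r in REGIONS:
            for g in GENDERS:
                counts[StratumKey(r, g, cohort)] = int(cells[i])
                i += 1
    return counts


def generate_population(config: SyntheticConfig) -> dict[int, PopulationTable]:
    """Generate stratified population tables for every configured horizon.

    Construction guarantees the headline aggregates exactly: the grand total
    at each horizon is ``round(base_total x overall_growth)``, and any cohort
    with an explicit growth multiplier hits ``round(base_cohort_total x
    multiplier)`` exactly.  Growth (the increment over the 2007 base) is
    allocated across cells proportionally to base size, a regional tilt toward
    the configured 2026 region shares, and seeded log-normal jitter — so cell
    trajectories are heterogeneous while every published aggregate is exact.
    With all multipliers equal to 1 each horizon equals the 2007 base
    identically.
    """
    base = _base_population_2007(config)
    base_total = sum(base.values())
    rng = config.rng(_STREAM_POPULATION)
    out: dict[int, PopulationTable] = {}

    for year in sorted(config.overall_growth):
        g = config.overall_growth[year]
        target_total = int(round(base_total * g))
        cohort_mults = config.cohort_growth.get(year, {})

        # cohort-level targets: pinned cohorts exact, rest share the remainder
        base_cohort = {c: sum(base[k] for k in all_strata() if k.cohort is c) for c in COHORTS}
        targets: dict[Cohort, int] = {}
        for c, m in cohort_mults.items():
            targets[c] = int(round(base_cohort[c] * m))
        rest = [c for c in COHORTS if c not in targets]
        remainder = target_total - sum(targets.values())
        if remainder < 0:
            raise ValueError(f"cohort growth multipliers for {year} exceed the overall total")
        if rest:
            rest_targets = _apportion(remainder, np.array([base_cohort[c] for c in rest], float))
            targets.update(dict(zip(rest, rest_targets)))

        rfac = _region_factor(config, year)
        counts: dict[StratumKey, int] = {}
        for c in COHORTS:
            keys = [StratumKey(r, g_, c) for r in REGIONS for g_ in GENDERS]
            base_cells = np.array([base[k] for k in keys], dtype=float)
            increment = int(targets[c]) - int(base_cohort[c])
            if increment == 0:
                alloc = np.zeros(len(keys), dtype=np.int64)
            else:
                jitter = (rng.lognormal(0.0, config.population_jitter_sd, size=len(keys))
                          if config.population_jitter_sd > 0 else np.ones(len(keys)))
                w = base_cells * np.array([rfac[k.region] for k in keys]) * jitter
                alloc = np.sign(increment) * _apportion(abs(increment), w)
            cells = base_cells.astype(np.int64) + alloc
            if (cells < 0).any():
                raise ValueError(f"population decline for cohort {c} @{year} exceeds base cells")
            counts.update({k: int(v) for k, v in zip(keys, cells)})
        out[year] = PopulationTable(horizon=year, counts=counts)
    return out


# ---------------------------------------------------------------------------
# coverage history
# ---------------------------------------------------------------------------

def generate_coverage_history(config: SyntheticConfig) -> pd.Series:
    """Generate the annual national coverage series 1996–2011.

    The series is constructed, not freely sampled: its min, mean and max match
    ``coverage_history_range`` to within 1e-9, anchored years (default: the
    published 30.1% in 2007 and 36.9% in 2011) take their anchor values
    exactly, and every value lies in [min, max].
    """
    lo, mean, hi = config.coverage_history_range
    years = list(COVERAGE_YEARS)
    n = len(years)
    anchors = dict(config.coverage_anchors)
    for y, v in anchors.items():
        if y not in years:
            raise ValueError(f"coverage anchor year {y} outside 1996–2011")
        if not (lo - 1e-12 <= v <= hi + 1e-12):
            raise ValueError(f"coverage anchor {v} for {y} outside the configured range")
    rng = config.rng(_STREAM_COVERAGE)

    values: dict[int, float] = dict(anchors)
    free_years = [y for y in years if y not in values]

    # pin the extremes (reusing an anchor year if it already attains one)
    need_min = not any(abs(v - lo) <= 1e-12 for v in values.values())
    need_max = not any(abs(v - hi) <= 1e-12 for v in values.values())
    pin_years = list(rng.permutation(free_years))
    if need_min:
        values[pin_years.pop()] = lo
    if need_max:
        values[pin_years.pop()] = hi
    free_years = [y for y in free_years if y not in values]

    for y in free_years:
        values[y] = float(rng.uniform(lo, hi))

    # affine squeeze of the free values to hit the configured mean exactly
    target_free = n * mean - sum(values[y] for y in years if y not in free_years)
    if free_years:
        cur = sum(values[y] for y in free_years)
        m = len(free_years)
        if target_free < cur:  # squeeze toward the minimum: x' = lo + a(x - lo)
            denom = cur - m * lo
            alpha = 0.0 if denom <= 0 else (target_free - m * lo) / denom
        else:                  # squeeze toward the maximum: x' = hi - a(hi - x)
            denom = m * hi - cur
            alpha = 0.0 if denom <= 0 else (m * hi - target_free) / denom
        if not (0.0 <= alpha <= 1.0 + 1e-12):
            raise ValueError("configured coverage mean is unattainable with the given anchors")
        if target_free < cur:
            for y in free_years:
                values[y] = lo + alpha * (values[y] - lo)
        else:
            for y in free_years:
                values[y] = hi - alpha * (hi - values[y])
    else:
        if abs(target_free) > 1e-9:
            raise ValueError("configured coverage mean inconsistent with anchors")

    series = pd.Series([values[y] for y in years], index=pd.Index(years, name="year"),
                       name="coverage")
    return series
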