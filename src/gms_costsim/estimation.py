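"""Stratified estimation of claims rates and average cost per claim.

The model's two behavioural inputs are estimated as simple stratified
proportions and means — there is no regression: the claims rate of a stratum
is claimants / eligible persons, and the average cost per claim is total
claimant cost / claimants.  Uncertainty enters through min/mean/max scenario
tables built from 95% confidence intervals (normal approximation, z = 1.96;
strata carry hundreds of observations, so a t quantile would be
indistinguishable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .strata import (
    Cohort,
    Gender,
    RateTable,
    Region,
    StratumKey,
    all_strata,
)

__all__ = [
    "ScenarioSet",
    "estimate_claims_rate",
    "estimate_avg_cost",
    "ci95_scenarios",
    "percent_change",
    "Z_95",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96
#: strictly positive floor for clamped avg-cost lower bounds (1 cent)
_COST_FLOOR = 0.01


@dataclass
class ScenarioSet:
    """Minimum / mean / maximum variants of one rate table.

    ``minimum`` and ``maximum`` are the lower and upper 95%-CI bounds around
    the point estimate (``method="ci95"``) or historical extremes
    (``method="historical_extremes"``); cell-wise ``minimum <= mean <=
    maximum`` always holds.
    """

    minimum: RateTable
    mean: RateTable
    maximum: RateTable
    method: str = "ci95"

    def __post_init__(self) -> None:
        kinds = {self.minimum.kind, self.mean.kind, self.maximum.kind}
        if len(kinds) != 1:
            raise ValueError(f"scenario tables have mixed kinds: {kinds}")
        for key in all_strata():
            lo, mid, hi = self.minimum[key], self.mean[key], self.maximum[key]
            if not (lo <= mid + 1e-12 and mid <= hi + 1e-12):
                raise ValueError(f"scenario ordering violated at {key}: "
                                 f"{lo} <= {mid} <= {hi} fails")

    def __getitem__(self, scenario: int | str) -> RateTable:
        """Scenario 1 = minimum, 2 = mean, 3 = maximum (or by name)."""
        mapping = {1: self.minimum, 2: self.mean, 3: self.maximum,
                   "minimum": self.minimum, "mean": self.mean, "maximum": self.maximum}
        try:
            return mapping[scenario]
        except KeyError:
            raise KeyError(f"unknown scenario {scenario!r}; use 1/2/3 or "
                           f"minimum/mean/maximum") from None


def estimate_claims_rate(
    claimants: Mapping[StratumKey, int],
    eligible: Mapping[StratumKey, int],
) -> RateTable:
    """Per-stratum claims rate = claimants / eligible persons.

    The printed-style marginals (row, cohort, national) are the pooled ratios
    sum(claimants)/sum(eligible), e.g. the national 2007 figures 1,225,131 /
    1,276,178 give 0.96.
    """
    values: dict[StratumKey, float] = {}
    for key in all_strata():
        n_elig = int(eligible.get(key, 0))
        n_claim = int(claimants.get(key, 0))
        if n_elig <= 0:
            raise ValueError(f"eligible count must be > 0 at {key}")
        if n_claim > n_elig:
            raise ValueError(f"claimants ({n_claim}) exceed eligible ({n_elig}) at {key}: "
                             "corrupted input")
        if n_claim < 0:
            raise ValueError(f"negative claimant count at {key}")
        values[key] = n_claim / n_elig

    def pooled(keys: list[StratumKey]) -> float:
        return sum(claimants[k] for k in keys) / sum(eligible[k] for k in keys)

    row_totals = {(r, g): pooled([StratumKey(r, g, c) for c in Cohort])
                  for r in Region for g in Gender}
    cohort_totals = {c: pooled([StratumKey(r, g, c) for r in Region for g in Gender])
                     for c in Cohort}
    return RateTable("claims_rate", values, row_totals=row_totals,
                     cohort_totals=cohort_totals, grand_total=pooled(list(all_strata())))


def estimate_avg_cost(
    claims: pd.DataFrame,
    claimants: Mapping[StratumKey, int] | None = None,
) -> RateTable:
    """Per-stratum average pharmacy cost per claimant.

    With ``claimants`` supplied the stratum value is total cost / claimant
    count (the scheme's definition); without it, the per-record mean of
    ``total_cost`` (equivalent when each record is one claimant).  The grand
    total is overall cost / overall claimants.  A stratum with no claims is an
    error naming the stratum.
    """
    grouped = claims.groupby(["region", "gender", "cohort"], observed=False)["total_cost"]
    sums = grouped.sum()
    counts = grouped.size()

    values: dict[StratumKey, float] = {}
    for key in all_strata():
        label = (key.region.value, key.gender.value, key.cohort.value)
        n_rec = int(counts.get(label, 0))
        if n_rec == 0:
            raise ValueError(f"no claims in stratum {key}")
        denom = int(claimants[key]) if claimants is not None else n_rec
        if denom <= 0:
            raise ValueError(f"claimant count must be > 0 at {key}")
        values[key] = float(sums[label]) / denom

    total_cost = float(sums.sum())
    total_claimants = (sum(int(claimants[k]) for k in all_strata())
                       if claimants is not None else int(counts.sum()))
    return RateTable("avg_cost", values, grand_total=total_cost / total_claimants)


def ci95_scenarios(
    point: RateTable,
    dispersion: Mapping[StratumKey, float],
) -> ScenarioSet:
    """Build min/mean/max scenario tables from per-stratum standard errors.

    minimum = point - 1.96*SE and maximum = point + 1.96*SE, clamped to the
    table kind's domain ([0, 1] for rates and coverage, > 0 for costs);
    clamping is logged.  Before clamping the interval is symmetric.
    """
    lo_vals: dict[StratumKey, float] = {}
    hi_vals: dict[StratumKey, float] = {}
    is_fraction = point.kind in ("claims_rate", "coverage")
    n_clamped = 0
    for key in all_strata():
        se = float(dispersion[key])
        if se < 0 or not math.isfinite(se):
            raise ValueError(f"standard error must be finite and >= 0 at {key}")
        lo = point[key] - Z_95 * se
        hi = point[key] + Z_95 * se
        if is_fraction:
            clo, chi = max(lo, 0.0), min(hi, 1.0)
        else:
            clo, chi = max(lo, _COST_FLOOR), hi
        if clo != lo or chi != hi:
            n_clamped += 1
        lo_vals[key], hi_vals[key] = clo, chi
    if n_clamped:
        logger.info("ci95_scenarios: clamped %d of %d strata to the %s domain",
                    n_clamped, len(lo_vals), point.kind)
    return ScenarioSet(
        minimum=RateTable(point.kind, lo_vals),
        mean=RateTable(point.kind, dict(point.values),
                       row_totals=dict(point.row_totals),
                       cohort_totals=dict(point.cohort_totals),
                       grand_total=point.grand_total),
        maximum=RateTable(point.kind, hi_vals),
        method="ci95",
    )


def binomial_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return math.sqrt(p * (1.0 - p) / n)


def claims_rate_scenarios(rate: RateTable, eligible: Mapping[StratumKey, int]) -> ScenarioSet:
    """CI-95 scenarios for a claims-rate table under binomial sampling error."""
    se = {k: binomial_se(rate[k], int(eligible[k])) for k in all_strata()}
    return ci95_scenarios(rate, se)


def avg_cost_scenarios(point: RateTable, claims: pd.DataFrame) -> ScenarioSet:
    """CI-95 scenarios for an average-cost table; SE = sample SD / sqrt(n)."""
    grouped = claims.groupby(["region", "gender", "cohort"], observed=False)["total_cost"]
    sd = grouped.std(ddof=1)
    n = grouped.size()
    se: dict[StratumKey, float] = {}
    for key in all_strata():
        label = (key.region.value, key.gender.value, key.cohort.value)
        count = int(n.get(label, 0))
        if count == 0:
            raise ValueError(f"no claims in stratum {key}")
        s = float(sd.get(label, 0.0))
        se[key] = 0.0 if count < 2 or math.isnan(s) else s / math.sqrt(count)
    return ci95_scenarios(point, se)


def percent_change(start: float, end: float) -> float:
    """Percent change 100*(end - start)/start, reported to 1 d.p."""
    if start <= 0:
        raise ValueError("start must be > 0")
    return round(100.0 * (end - start) / start, 1)
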