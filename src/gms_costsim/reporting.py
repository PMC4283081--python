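"""Descriptive statistics, main-effects decomposition and scenario tables.

The simulator's output is summarised three ways, mirroring how the study
presents its results: a nine-statistic descriptive row per ensemble
(n, mean, SE of the mean, SD, min, quartiles, max), a main-effects
decomposition of mean cost by region, gender and age cohort with the factors
ranked by the spread of their level means, and a scenario-by-horizon
comparison table with total-cost projections.  Histograms are emitted as
binned tables, not images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mc_engine import SimulationResult
from .strata import Cohort, Gender, Region

__all__ = [
    "DescriptiveRow",
    "MainEffects",
    "describe",
    "main_effects",
    "scenario_report",
    "histogram_table",
    "QUANTILE_METHOD",
]

#: numpy quantile method; "weibull" is Hazen/Minitab-style type 6 interpolation
QUANTILE_METHOD = "weibull"


@dataclass(frozen=True)
class DescriptiveRow:
    """The nine descriptive statistics of one cost ensemble (€ per person)."""

    n: int
    mean: float
    se_mean: float
    st_dev: float
    min: float
    q1: float
    median: float
    q3: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n, "mean": self.mean, "se_mean": self.se_mean,
            "st_dev": self.st_dev, "min": self.min, "q1": self.q1,
            "median": self.median, "q3": self.q3, "max": self.max,
        }


def describe(draws: Sequence[float] | np.ndarray,
             quantile_method: str = QUANTILE_METHOD) -> DescriptiveRow:
    """Descriptive row for a vector of cost draws.

    Quartiles use linear interpolation between order statistics
    (``quantile_method``, default type-6/"weibull"); SD uses the n-1
    denominator and the SE of the mean is SD/sqrt(n).  Order-invariant.
    """
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("describe requires at least one draw")
    n = int(x.size)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q1, med, q3 = (float(q) for q in
                   np.quantile(x, [0.25, 0.5, 0.75], method=quantile_method))
    return DescriptiveRow(
        n=n,
        mean=float(np.mean(x)),
        se_mean=sd / math.sqrt(n),
        st_dev=sd,
        min=float(np.min(x)),
        q1=q1,
        median=med,
        q3=q3,
        max=float(np.max(x)),
    )


@dataclass
class MainEffects:
    """Mean simulated cost by level of each categorical factor.

    Levels with no draws are absent from the mapping (not reported as zero).
    ``factor_ranking`` orders the factors by the range of their level means,
    largest first — the factor whose levels spread the most is the dominant
    cost driver.
    """

    by_region: dict[Region, float]
    by_gender: dict[Gender, float]
    by_cohort: dict[Cohort, float]
    grand_mean: float

    def factor_range(self, factor: str) -> float:
        levels = {"region": self.by_region, "gender": self.by_gender,
                  "cohort": self.by_cohort}[factor]
        vals = list(levels.values())
        return max(vals) - min(vals) if vals else 0.0

    @property
    def factor_ranking(self) -> list[str]:
        return sorted(("region", "gender", "cohort"),
                      key=self.factor_range, reverse=True)


def main_effects(result: SimulationResult) -> MainEffects:
    """Decompose mean simulated cost by region, gender and age cohort.

    Each factor's level mean is the plain mean of the draws falling in that
    level; weighting level means by their draw counts therefore recombines to
    the grand mean exactly.
    """
    costs = np.asarray(result.costs, dtype=float)
    idx = np.asarray(result.stratum_index)

    def level_means(levels, accessor) -> dict:
        out = {}
        stratum_level = np.array([levels.index(accessor(s)) for s in result.strata])
        draw_level = stratum_level[idx]
        for li, level in enumerate(levels):
            mask = draw_level == li
            if mask.any():
                out[level] = float(costs[mask].mean())
        return out

    return MainEffects(
        by_region=level_means(tuple(Region), lambda s: s.region),
        by_gender=level_means(tuple(Gender), lambda s: s.gender),
        by_cohort=level_means(tuple(Cohort), lambda s: s.cohort),
        grand_mean=float(costs.mean()),
    )


def scenario_report(
    results: Mapping[tuple[int, int], SimulationResult],
    total_costs: Mapping[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Comparison table over (scenario, horizon) cells.

    One descriptive row per simulated ensemble, keyed by scenario (1/2/3 =
    minimum/mean/maximum) and horizon year, with the deterministic per-person
    expectation and, when supplied, the projected total scheme cost in
    € million.
    """
    if not results:
        raise ValueError("scenario_report requires at least one result")
    rows = []
    for (scenario, horizon), res in sorted(results.items()):
        row = {"scenario": scenario, "horizon": horizon}
        row.update(describe(res.costs).as_dict())
        row["deterministic_expectation"] = res.deterministic_expectation
        if total_costs is not None and (scenario, horizon) in total_costs:
            row["total_cost_m"] = total_costs[(scenario, horizon)] / 1e6
        rows.append(row)
    return pd.DataFrame(rows)


def histogram_table(draws: Sequence[float] | np.ndarray, bins: int = 30) -> pd.DataFrame:
    """Binned cost histogram as a table (lower/upper edge, count, frequency)."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("histogram requires at least one draw")
    counts, edges = np.histogram(x, bins=bins)
    return pd.DataFrame({
        "lower": edges[:-1],
        "upper": edges[1:],
        "count": counts,
        "frequency": counts / x.size,
    })
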