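"""Projection of coverage, eligible persons and average claim cost to 2016–2026.

Coverage (the fraction of the population holding a medical card) is projected
by carrying each stratum's anchored eligible-person count forward against the
projected population.  Where demographic decline pushes a raw rate to 1.00 or
above — which happens in the oldest cohorts — an adjustment factor λ caps the
rate strictly below 1.00, since coverage is a proportion of the living
population.  Average cost per claim is grown at its historical compound rate;
the claims rate is held at its base-year level throughout, reflecting the
observed stability of the national claims rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from .strata import PopulationTable, RateTable, StratumKey, all_strata

__all__ = [
    "DEFAULT_LAMBDA",
    "CoverageProjection",
    "GrowthModel",
    "adjust_coverage",
    "project_coverage",
    "extrapolate_avg_cost",
    "fit_historical_growth",
]

logger = logging.getLogger(__name__)

#: default coverage adjustment factor; must lie in (0, 0.99]
DEFAULT_LAMBDA = 0.99


def adjust_coverage(raw_rate: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Cap a raw coverage rate below 1.00.

    Rates below 1.00 pass through unchanged; a rate of 1.00 or above (e.g. a
    projected population of 100 with 105 projected eligible persons, raw rate
    1.05) is replaced by ``lam``, a value strictly below 1.00.
    """
    if not 0.0 < lam <= 0.99:
        raise ValueError(f"lambda must be in (0, 0.99], got {lam}")
    if raw_rate < 0:
        raise ValueError(f"raw coverage rate must be >= 0, got {raw_rate}")
    return raw_rate if raw_rate < 1.0 else lam


@dataclass
class CoverageProjection:
    """Projected coverage and eligible persons at one horizon."""

    horizon: int
    coverage: RateTable
    eligible: dict[StratumKey, float]     # fractional internally
    national_rate: float

    def eligible_persons(self) -> dict[StratumKey, int]:
        """Eligible counts rounded half-up to whole persons (reporting only)."""
        return {k: int(math.floor(v + 0.5)) for k, v in self.eligible.items()}

    def total_eligible(self) -> float:
        return sum(self.eligible.values())


def project_coverage(
    base_coverage: RateTable,
    base_population: PopulationTable,
    populations: Mapping[int, PopulationTable],
    lam: float = DEFAULT_LAMBDA,
    eligible_growth: Mapping[int, float] | None = None,
) -> dict[int, CoverageProjection]:
    """Project coverage and eligible persons to each horizon.

    The anchor eligible count of a stratum is ``base_coverage x base
    population``.  At a horizon the raw rate is the (optionally grown) anchor
    count divided by the projected population; :func:`adjust_coverage` is then
    applied cell-wise, and eligible persons are recomputed from the adjusted
    rate.  ``eligible_growth`` optionally scales the anchor trajectory per
    horizon (default: carried forward flat).
    """
    if base_coverage.kind != "coverage":
        raise ValueError(f"base_coverage must be a coverage table, got {base_coverage.kind}")
    anchor = {k: base_coverage[k] * base_population[k] for k in all_strata()}
    out: dict[int, CoverageProjection] = {}
    for horizon in sorted(populations):
        pop = populations[horizon]
        mult = 1.0 if eligible_growth is None else float(eligible_growth.get(horizon, 1.0))
        if mult <= 0:
            raise ValueError(f"eligible growth multiplier for {horizon} must be > 0")
        values: dict[StratumKey, float] = {}
        eligible: dict[StratumKey, float] = {}
        n_capped = 0
        for key in all_strata():
            trajectory = anchor[key] * mult
            if pop[key] == 0:
                if trajectory > 0:
                    raise ValueError(f"zero population with positive eligible count at "
                                     f"{key} for horizon {horizon}")
                values[key] = 0.0
                eligible[key] = 0.0
                continue
            raw = trajectory / pop[key]
            adj = adjust_coverage(raw, lam)
            if adj != raw:
                n_capped += 1
            values[key] = adj
            eligible[key] = adj * pop[key]
        if n_capped:
            logger.info("project_coverage: capped %d strata at lambda=%s for %d",
                        n_capped, lam, horizon)
        national = sum(eligible.values()) / pop.total()
        out[horizon] = CoverageProjection(
            horizon=horizon,
            coverage=RateTable("coverage", values),
            eligible=eligible,
            national_rate=national,
        )
    return out


@dataclass
class GrowthModel:
    """Compound growth of average cost per claim from an anchor year.

    ``annual_growth`` is a single national rate or a per-stratum mapping;
    ``1 + annual_growth`` must be positive.
    """

    base: RateTable
    annual_growth: float | Mapping[StratumKey, float] = 0.0
    anchor_year: int = 2007

    def __post_init__(self) -> None:
        for g in self._rates().values():
            if 1.0 + g <= 0:
                raise ValueError(f"1 + annual_growth must be > 0, got growth {g}")

    def _rates(self) -> dict[StratumKey, float]:
        if isinstance(self.annual_growth, Mapping):
            return {k: float(self.annual_growth[k]) for k in all_strata()}
        return {k: float(self.annual_growth) for k in all_strata()}


def extrapolate_avg_cost(model: GrowthModel, horizon: int) -> RateTable:
    """Average-cost table at ``horizon``: base x (1 + growth)^(horizon - anchor).

    Multiplicative across horizons: growing to 2016 and then on to 2021 equals
    growing directly to 2021.
    """
    if horizon < model.anchor_year:
        raise ValueError(f"horizon {horizon} precedes anchor year {model.anchor_year}")
    years = horizon - model.anchor_year
    rates = model._rates()
    values = {k: model.base[k] * (1.0 + rates[k]) ** years for k in all_strata()}
    return RateTable("avg_cost", values)


def fit_historical_growth(series: Mapping[int, float]) -> float:
    """Geometric-mean annual growth of a national average-cost series.

    ``(last / first) ** (1 / (last_year - first_year)) - 1``; on an
    exact-compounding series this equals the generating rate (and coincides
    with a log-linear regression fit).
    """
    series = dict(series)  # accepts any Mapping, incl. a year-indexed Series
    if len(series) < 2:
        raise ValueError("need at least 2 years of data")
    years = sorted(series)
    first, last = float(series[years[0]]), float(series[years[-1]])
    if any(float(series[y]) <= 0 for y in years):
        raise ValueError("all values must be > 0")
    span = years[-1] - years[0]
    return (last / first) ** (1.0 / span) - 1.0
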