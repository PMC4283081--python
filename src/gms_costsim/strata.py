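"""Domain vocabulary and stratified tables for the GMS cost model.

The General Medical Services (GMS) scheme entitles Irish medical-card holders
to free prescription drugs.  Every quantity in the model — coverage, claims
rate, average cost per claim, population — is stratified by the same universe
of 160 cells: 8 former health-board regions x 2 genders x 10 age cohorts
(an "RGA class").  This module defines the closed, ordered enumerations for
those dimensions, the :class:`RateTable` / :class:`PopulationTable`
containers, the CSV fixture readers/writers, and marginal-consistency
validation.

Strata are always addressed by the ``(region, gender, cohort)`` triple;
no public contract uses positional indexing.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Region",
    "Gender",
    "Cohort",
    "StratumKey",
    "RateTable",
    "PopulationTable",
    "ConsistencyFlag",
    "ConsistencyReport",
    "all_strata",
    "load_rate_table",
    "write_rate_table",
    "fixture_path",
    "load_fixture",
    "validate_consistency",
    "write_csv_with_provenance",
    "N_STRATA",
]


class Region(str, Enum):
    """The 8 former (pre-2010) Irish health-board regions, in table order."""

    EASTERN = "Eastern"
    MIDLAND = "Midland"
    MID_WESTERN = "Mid-Western"
    NORTH_EASTERN = "North-Eastern"
    NORTH_WESTERN = "North-Western"
    SOUTH_EASTERN = "South-Eastern"
    SOUTHERN = "Southern"
    WESTERN = "Western"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Cohort(str, Enum):
    """HSE age cohorts, ascending; 75+ is open-ended."""

    C0_11 = "0-11"
    C12_15 = "12-15"
    C16_24 = "16-24"
    C25_34 = "25-34"
    C35_44 = "35-44"
    C45_54 = "45-54"
    C55_64 = "55-64"
    C65_69 = "65-69"
    C70_74 = "70-74"
    C75_PLUS = "75+"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


REGIONS: tuple[Region, ...] = tuple(Region)
GENDERS: tuple[Gender, ...] = tuple(Gender)
COHORTS: tuple[Cohort, ...] = tuple(Cohort)
N_STRATA = len(REGIONS) * len(GENDERS) * len(COHORTS)  # 160

#: Cohorts the model treats as "elderly" for coverage capping discussions.
ELDERLY_COHORTS: tuple[Cohort, ...] = (Cohort.C70_74, Cohort.C75_PLUS)

VALID_KINDS = ("claims_rate", "coverage", "avg_cost")
#: Table kinds whose values are dimensionless fractions in [0, 1].
FRACTION_KINDS = ("claims_rate", "coverage")


@dataclass(frozen=True, order=True)
class StratumKey:
    """One (region, gender, age-cohort) cell — the model's universal index."""

    region: Region
    gender: Gender
    cohort: Cohort

    def __str__(self) -> str:
        return f"{self.region.value}/{self.gender.value}/{self.cohort.value}"


def all_strata() -> Iterator[StratumKey]:
    """Yield the 160 strata in canonical order (region, then gender, then cohort)."""
    for region in REGIONS:
        for gender in GENDERS:
            for cohort in COHORTS:
                yield StratumKey(region, gender, cohort)


def _require_complete(values: Mapping[StratumKey, object], what: str) -> None:
    missing = [k for k in all_strata() if k not in values]
    if missing:
        raise ValueError(f"{what} incomplete: missing stratum {missing[0]} "
                         f"({len(missing)} of {N_STRATA} absent)")
    if len(values) != N_STRATA:
        extra = set(values) - set(all_strata())
        raise ValueError(f"{what} has {len(values)} keys, expected {N_STRATA}; "
                         f"unexpected: {sorted(map(str, extra))[:3]}")


@dataclass
class RateTable:
    """A complete per-stratum table of one model quantity.

    Parameters
    ----------
    kind:
        ``"claims_rate"`` or ``"coverage"`` (fractions in [0, 1]) or
        ``"avg_cost"`` (euro per claimant, strictly positive).
    values:
        Mapping over all 160 strata.
    row_totals, cohort_totals, grand_total:
        Optional printed (claimant-weighted) marginals carried through from a
        fixture.  They are transcriptions, never recomputed; see
        :func:`validate_consistency`.
    """

    kind: str
    values: dict[StratumKey, float]
    row_totals: dict[tuple[Region, Gender], float] = field(default_factory=dict)
    cohort_totals: dict[Cohort, float] = field(default_factory=dict)
    grand_total: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}; expected one of {VALID_KINDS}")
        _require_complete(self.values, f"{self.kind} table")
        for key, v in self.values.items():
            self._check_domain(key, float(v))
        self.values = {k: float(self.values[k]) for k in all_strata()}

    def _check_domain(self, key: StratumKey, v: float) -> None:
        if self.kind in FRACTION_KINDS:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.kind} value {v} out of [0, 1] at {key}")
        else:
            if not v > 0.0:
                raise ValueError(f"avg_cost value {v} not > 0 at {key}")

    def __getitem__(self, key: StratumKey) -> float:
        try:
            return self.values[key]
        except KeyError:
            raise KeyError(f"stratum {key} absent from {self.kind} table") from None

    def __iter__(self) -> Iterator[StratumKey]:
        return all_strata()

    def to_series(self) -> pd.Series:
        """Values as a Series indexed by (region, gender, cohort) labels."""
        idx = pd.MultiIndex.from_tuples(
            [(k.region.value, k.gender.value, k.cohort.value) for k in all_strata()],
            names=["region", "gender", "cohort"],
        )
        return pd.Series([self.values[k] for k in all_strata()], index=idx, name=self.kind)

    def map_values(self, fn) -> "RateTable":
        """A new table of the same kind with ``fn`` applied cell-wise (totals dropped)."""
        return RateTable(self.kind, {k: fn(v) for k, v in self.values.items()})

    def with_kind(self, kind: str) -> "RateTable":
        return RateTable(kind, dict(self.values))


@dataclass
class PopulationTable:
    """Persons per stratum at one projection horizon."""

    horizon: int
    counts: dict[StratumKey, int]

    def __post_init__(self) -> None:
        _require_complete(self.counts, f"population table ({self.horizon})")
        for key, n in self.counts.items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative population {n} at {key}")
        self.counts = {k: int(self.counts[k]) for k in all_strata()}
        if self.total() <= 0:
            raise ValueError("population grand total must be > 0")

    def __getitem__(self, key: StratumKey) -> int:
        return self.counts[key]

    def total(self) -> int:
        return sum(self.counts.values())

    def cohort_total(self, cohort: Cohort) -> int:
        return sum(n for k, n in self.counts.items() if k.cohort is cohort)

    def region_total(self, region: Region) -> int:
        return sum(n for k, n in self.counts.items() if k.region is region)

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            [(k.region.value, k.gender.value, k.cohort.value) for k in all_strata()],
            names=["region", "gender", "cohort"],
        )
        return pd.Series([self.counts[k] for k in all_strata()], index=idx,
                         name=f"population_{self.horizon}")


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

_COHORT_LABELS = tuple(c.value for c in COHORTS)
_TOTAL_MARK = "TOTAL"


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture CSV (``claims_rate_2007.csv``, ``avg_cost_2007.csv``)."""
    return Path(str(resources.files("gms_costsim").joinpath("data", name)))


def load_fixture(name: str) -> RateTable:
    kind = "claims_rate" if name.startswith("claims_rate") else "avg_cost"
    return load_rate_table(fixture_path(name), kind)


def _parse_number(token: str, row: int, col: str, domain_hint: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise ValueError(
            f"malformed numeric token {token!r} at data row {row}, column {col!r}"
        ) from None
    return v


def load_rate_table(path: str | Path, kind: str) -> RateTable:
    """Read a stratified rate-table fixture CSV.

    The format is one region–gender row per line with the ten cohort columns in
    ascending-age order, a printed ``total`` column, and one trailing ``TOTAL``
    row carrying the printed cohort marginals and grand total.  Comment lines
    start with ``#``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)
                if r and not (r[0] or "").lstrip().startswith("#")]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    header = [h.strip() for h in rows[0]]
    expected = ["region", "gender", *_COHORT_LABELS]
    if header[: len(expected)] != expected:
        raise ValueError(f"{path}: header {header[:12]} does not match expected "
                         f"cohort labels {expected}")
    has_total_col = len(header) > len(expected) and header[len(expected)] == "total"

    values: dict[StratumKey, float] = {}
    row_totals: dict[tuple[Region, Gender], float] = {}
    cohort_totals: dict[Cohort, float] = {}
    grand_total: float | None = None

    data_rows = rows[1:]
    if not data_rows:
        raise ValueError(f"{path}: no data rows")
    for i, row in enumerate(data_rows, start=1):
        cells = [c.strip() for c in row]
        if len(cells) < len(expected):
            raise ValueError(f"{path}: data row {i} has {len(cells)} fields, "
                             f"expected at least {len(expected)}")
        region_label, gender_label = cells[0], cells[1]
        if region_label == _TOTAL_MARK:
            for cohort, tok in zip(COHORTS, cells[2:12]):
                cohort_totals[cohort] = _parse_number(tok, i, cohort.value, kind)
            if has_total_col and len(cells) > 12 and cells[12]:
                grand_total = _parse_number(cells[12], i, "total", kind)
            continue
        try:
            region = Region(region_label)
        except ValueError:
            raise ValueError(f"{path}: unknown region {region_label!r} at data row {i}") from None
        try:
            gender = Gender(gender_label)
        except ValueError:
            raise ValueError(f"{path}: unknown gender {gender_label!r} at data row {i}") from None
        for cohort, tok in zip(COHORTS, cells[2:12]):
            key = StratumKey(region, gender, cohort)
            values[key] = _parse_number(tok, i, cohort.value, kind)
        if has_total_col and len(cells) > 12 and cells[12]:
            row_totals[(region, gender)] = _parse_number(cells[12], i, "total", kind)

    n_rows = len({(r, g) for (r, g) in ((k.region, k.gender) for k in values)})
    if n_rows != len(REGIONS) * len(GENDERS):
        raise ValueError(f"{path}: found {n_rows} region–gender rows, expected 16")
    return RateTable(kind, values, row_totals=row_totals,
                     cohort_totals=cohort_totals, grand_total=grand_total)


def _fmt(v: float) -> str:
    # shortest representation that round-trips the float exactly
    return repr(float(v))


def write_rate_table(table: RateTable, path: str | Path) -> None:
    """Write a RateTable in the fixture CSV format (round-trips bit-exactly)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "gender", *_COHORT_LABELS, "total"])
        for region in REGIONS:
            for gender in GENDERS:
                row = [region.value, gender.value]
                row += [_fmt(table.values[StratumKey(region, gender, c)]) for c in COHORTS]
                rt = table.row_totals.get((region, gender))
                row.append("" if rt is None else _fmt(rt))
                w.writerow(row)
        if table.cohort_totals or table.grand_total is not None:
            row = [_TOTAL_MARK, "all"]
            row += ["" if (t := table.cohort_totals.get(c)) is None else _fmt(t)
                    for c in COHORTS]
            row.append("" if table.grand_total is None else _fmt(table.grand_total))
            w.writerow(row)


# ---------------------------------------------------------------------------
# marginal consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyFlag:
    marginal: str          # e.g. "row North-Western/female", "cohort 75+", "grand"
    printed: float
    recomputed: float
    rel_diff: float


@dataclass
class ConsistencyReport:
    tolerance: float
    flags: list[ConsistencyFlag]

    @property
    def ok(self) -> bool:
        return not self.flags


def _weighted_mean(pairs: Iterable[tuple[float, float]]) -> float | None:
    num = den = 0.0
    for v, w in pairs:
        num += v * w
        den += w
    return None if den == 0 else num / den


def validate_consistency(
    table: RateTable,
    weights: PopulationTable | Mapping[StratumKey, float],
    tolerance: float = 0.005,
) -> ConsistencyReport:
    """Check printed marginals against weight-recomputed ones (report-only).

    Printed totals in the source tables are claimant-weighted with weights that
    are not published, so a recomputation under *any* supplied weights is a
    plausibility check, not a proof: rows whose printed total cannot be
    reproduced within ``tolerance`` (relative) are flagged, and the table is
    never mutated.
    """
    w = weights.counts if isinstance(weights, PopulationTable) else dict(weights)
    flags: list[ConsistencyFlag] = []

    def check(name: str, printed: float | None, keys: list[StratumKey]) -> None:
        if printed is None:
            return
        recomputed = _weighted_mean((table.values[k], float(w.get(k, 0.0))) for k in keys)
        if recomputed is None:
            return
        rel = abs(recomputed - printed) / abs(printed) if printed else abs(recomputed)
        if rel > tolerance:
            flags.append(ConsistencyFlag(name, printed, recomputed, rel))

    for region in REGIONS:
        for gender in GENDERS:
            keys = [StratumKey(region, gender, c) for c in COHORTS]
            check(f"row {region.value}/{gender.value}",
                  table.row_totals.get((region, gender)), keys)
    for cohort in COHORTS:
        keys = [StratumKey(r, g, cohort) for r in REGIONS for g in GENDERS]
        check(f"cohort {cohort.value}", table.cohort_totals.get(cohort), keys)
    check("grand", table.grand_total, list(all_strata()))
    return ConsistencyReport(tolerance=tolerance, flags=flags)


# ---------------------------------------------------------------------------
# provenance-stamped CSV output
# ---------------------------------------------------------------------------

def _short_hash(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_csv_with_provenance(df: pd.DataFrame, path: str | Path,
                              seed: int | None = None,
                              config_repr: str | None = None) -> None:
    """Write a DataFrame as CSV with a one-line ``#`` provenance header.

    The header records the packaged-fixture hashes, the RNG seed and a hash of
    the configuration so any output file can be traced back to its inputs.
    """
    fix_hash = _short_hash(
        fixture_path("claims_rate_2007.csv").read_text()
        + fixture_path("avg_cost_2007.csv").read_text()
    )
    cfg_hash = _short_hash(config_repr) if config_repr is not None else "none"
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# provenance: fixtures={fix_hash} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=False)
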