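"""Aggregation of regional indoor-radon surveys.

Individual surveys report an arithmetic-mean radon concentration for one
building function (homes, schools, civic/provincial/federal buildings,
senior residences) in one city, region or province.  National summary
statistics per building class are obtained in two stages:

1. surveys of the same class within one region are pooled with weights
   proportional to the number of places tested, and
2. regional pooled means are combined with weights proportional to the
   region's census population.

Regions with no survey for a class simply do not contribute to that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SurveyRecord",
    "RegionPooled",
    "DEFAULT_CLASS_MAP",
    "BUILDING_CLASSES",
    "EXCLUDED",
    "classify_record",
    "pool_within_region",
    "population_weighted_mean",
    "national_summary",
    "load_surveys",
    "table1_surveys",
]

#: Building classes used in the national assessment.
BUILDING_CLASSES = ("home", "school", "public")

#: Sentinel returned by :func:`classify_record` for functions outside the
#: assessment.
EXCLUDED = "excluded"

#: Default building-function -> building-class map.  Civic, provincial and
#: federal buildings are all treated as public buildings.  Senior residences
#: are dwellings: they are excluded from the public-building class but
#: counted with homes, which reproduces the published national counts
#: (homes 7866, schools 1132, public 1668).
DEFAULT_CLASS_MAP: Mapping[str, str] = {
    "home": "home",
    "school": "school",
    "public": "public",
    "senior_housing": "home",
}


@dataclass(frozen=True)
class SurveyRecord:
    """One radon survey: one building function in one region."""

    region: str
    population: int
    building_function: str
    n_tested: int
    mean_rn: float
    sd: float | None = None
    range_low: float | None = None
    range_high: float | None = None

    def __post_init__(self) -> None:
        if self.n_tested < 1:
            raise ValueError(f"n_tested must be >= 1, got {self.n_tested}")
        if self.mean_rn < 0:
            raise ValueError(f"mean_rn must be >= 0, got {self.mean_rn}")
        if self.population <= 0:
            raise ValueError(f"population must be > 0, got {self.population}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class RegionPooled:
    """Pooled survey result for one building class in one region."""

    region: str
    population: int
    building_class: str
    n_total: int
    pooled_mean: float


class ClassificationError(KeyError):
    """A building function has no entry in the class map."""


def classify_record(
    record: SurveyRecord,
    mapping: Mapping[str, str] = DEFAULT_CLASS_MAP,
    default: str | None = None,
) -> str:
    """Return the building class for ``record``, or ``"excluded"``.

    ``mapping`` sends building functions to classes; a function may also be
    mapped to :data:`EXCLUDED` explicitly.  A function absent from the map
    falls back to ``default``; with no default this raises
    :class:`ClassificationError`.
    """
    func = record.building_function
    if func in mapping:
        return mapping[func]
    if default is not None:
        return default
    raise ClassificationError(
        f"building function {func!r} is not in the class map and no "
        "default was given"
    )


def pool_within_region(records: Iterable[SurveyRecord]) -> RegionPooled:
    """Pool same-region, same-class surveys, weighting by measurement count.

    The pooled mean is the count-weighted mean
    ``sum(n_i * m_i) / sum(n_i)``, i.e. the arithmetic mean that would be
    obtained by concatenating the individual survey samples.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot pool an empty list of survey records")
    regions = {r.region for r in records}
    if len(regions) > 1:
        raise ValueError(f"records span multiple regions: {sorted(regions)}")
    n_total = sum(r.n_tested for r in records)
    pooled = sum(r.n_tested * r.mean_rn for r in records) / n_total
    first = records[0]
    return RegionPooled(
        region=first.region,
        population=first.population,
        building_class=first.building_function,
        n_total=n_total,
        pooled_mean=pooled,
    )


def population_weighted_mean(pooled: Iterable[RegionPooled]) -> float:
    """Population-weighted mean concentration over regional pooled results."""
    pooled = list(pooled)
    if not pooled:
        raise ValueError("no regional results to weight")
    seen: set[str] = set()
    for p in pooled:
        if p.region in seen:
            raise ValueError(f"region {p.region!r} appears more than once")
        seen.add(p.region)
    total_pop = sum(p.population for p in pooled)
    if total_pop <= 0:
        raise ValueError("total population is zero")
    return sum(p.population * p.pooled_mean for p in pooled) / total_pop


def national_summary(
    records: Iterable[SurveyRecord],
    mapping: Mapping[str, str] = DEFAULT_CLASS_MAP,
) -> dict[str, dict[str, float]]:
    """Per-class national counts and population-weighted mean concentrations.

    Returns ``{building_class: {"n_total": int, "weighted_mean": float}}``.
    Classes with no contributing survey are absent from the result.  The
    weighted mean is kept at full precision; round for display.
    """
    by_class: dict[str, dict[str, list[SurveyRecord]]] = {}
    for rec in records:
        cls = classify_record(rec, mapping)
        if cls == EXCLUDED:
            continue
        by_class.setdefault(cls, {}).setdefault(rec.region, []).append(rec)

    out: dict[str, dict[str, float]] = {}
    for cls, regions in by_class.items():
        pooled = []
        for region_records in regions.values():
            p = pool_within_region(region_records)
            pooled.append(
                RegionPooled(p.region, p.population, cls, p.n_total, p.pooled_mean)
            )
        out[cls] = {
            "n_total": sum(p.n_total for p in pooled),
            "weighted_mean": population_weighted_mean(pooled),
        }
    return out


def load_surveys(path: str | Path) -> list[SurveyRecord]:
    """Read survey records from CSV.

    Expected header:
    ``region,population,building_function,n_tested,mean_rn,sd,range_low,range_high``
    with optional fields left blank (below-detection range lows are blank).
    """
    df = pd.read_csv(path)
    required = {"region", "population", "building_function", "n_tested", "mean_rn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey CSV {path} is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"survey CSV {path} contains no records")

    def _opt(row: pd.Series, col: str) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    return [
        SurveyRecord(
            region=str(row["region"]),
            population=int(row["population"]),
            building_function=str(row["building_function"]),
            n_tested=int(row["n_tested"]),
            mean_rn=float(row["mean_rn"]),
            sd=_opt(row, "sd"),
            range_low=_opt(row, "range_low"),
            range_high=_opt(row, "range_high"),
        )
        for _, row in df.iterrows()
    ]


def table1_surveys() -> list[SurveyRecord]:
    """The packaged Canadian regional survey compilation."""
    return load_surveys(Path(__file__).parent / "data" / "table1_surveys.csv")
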