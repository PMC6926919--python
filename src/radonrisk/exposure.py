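"""Radon-progeny exposure in microenvironments.

Health risk tracks the radon progeny rather than the gas, so measured radon
concentrations are converted to equilibrium-equivalent concentrations
(EEC = radon x F_eq).  Combining each age group's daily time budget across
four microenvironments (home, indoors away from home, outdoors, vehicle)
with the EEC of each location gives annual exposures in h Bq/m3, which
convert to working level months (WLM) via 1 WLM = 6.37e5 h Bq/m3 EEC.

A lifetime exposure history assigns each year of life (0..109) its age
group's annual per-location exposure; time-since-exposure windows over that
history feed the excess-relative-risk model in :mod:`radonrisk.risk`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "AGE_GROUPS",
    "AGE_GROUP_SPANS",
    "LIFESPAN",
    "WLM_H_BQM3",
    "DAYS_PER_YEAR",
    "MicroenvironmentEEC",
    "TimeActivityPattern",
    "AgeGroupExposure",
    "ExposureHistory",
    "eec",
    "annual_exposure",
    "age_group_exposure",
    "to_wlm",
    "build_lifetime_history",
    "exposure_windows",
    "age_group_for_age",
    "load_time_activity",
    "table2_patterns",
    "round_half_up",
]

#: Microenvironments, in reporting order.
LOCATIONS = ("home", "indoors_away", "outdoors", "vehicle")

#: Age groups in life-course order.
AGE_GROUPS = ("infant", "young_child", "child", "adolescent", "adult", "senior")

#: Inclusive year-of-life spans per age group (lifespan 110 y: ages 0..109).
AGE_GROUP_SPANS: Mapping[str, tuple[int, int]] = {
    "infant": (0, 0),
    "young_child": (1, 4),
    "child": (5, 11),
    "adolescent": (12, 19),
    "adult": (20, 59),
    "senior": (60, 109),
}

LIFESPAN = 110

#: h Bq/m3 of EEC per working level month.
WLM_H_BQM3 = 6.37e5

DAYS_PER_YEAR = 365

#: Exposure lag: the most recent years carry no lung-cancer risk.
LAG_YEARS = 5


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for display).

    A small relative epsilon absorbs binary representation error in values
    that are exact decimal ties (0.95 * 6 * 365 is 2080.5 in decimal but
    sits just below it in binary).
    """
    y = abs(x) * 10.0**ndigits
    eps = 1e-9 * max(1.0, y)
    return math.copysign(math.floor(y + 0.5 + eps) / 10.0**ndigits, x)


def eec(radon: float, f_eq: float) -> float:
    """Equilibrium-equivalent progeny concentration, Bq/m3.

    ``radon`` is the radon gas concentration in Bq/m3 and ``f_eq`` the
    equilibrium factor in (0, 1].
    """
    if radon < 0:
        raise ValueError(f"radon concentration must be >= 0, got {radon}")
    if not 0 < f_eq <= 1:
        raise ValueError(f"equilibrium factor must be in (0, 1], got {f_eq}")
    return radon * f_eq


def annual_exposure(
    hours_per_day: float, eec_bqm3: float, days_per_year: float = DAYS_PER_YEAR
) -> float:
    """Annual exposure in h Bq/m3 of EEC, at full precision."""
    if not 0 <= hours_per_day <= 24:
        raise ValueError(f"hours per day must be in [0, 24], got {hours_per_day}")
    return hours_per_day * eec_bqm3 * days_per_year


def to_wlm(exposure_h_bqm3: float, wlm_h_bqm3: float = WLM_H_BQM3) -> float:
    """Convert h Bq/m3 of EEC to working level months."""
    if exposure_h_bqm3 < 0:
        raise ValueError(f"exposure must be >= 0, got {exposure_h_bqm3}")
    return exposure_h_bqm3 / wlm_h_bqm3


@dataclass(frozen=True)
class MicroenvironmentEEC:
    """A location class with its radon level and equilibrium factor."""

    location: str
    radon: float
    f_eq: float
    eec: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "eec", eec(self.radon, self.f_eq))


@dataclass(frozen=True)
class TimeActivityPattern:
    """Daily time budget and location EECs for one age group.

    The EEC map is age-group specific because the "indoors away from home"
    environment differs: public buildings for infants, (mostly home-based)
    daycares for young children, schools for children and adolescents,
    workplaces for adults and seniors.
    """

    age_group: str
    hours: Mapping[str, float]
    eec_map: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if set(self.hours) != set(LOCATIONS):
            raise ValueError(f"hours must cover exactly {LOCATIONS}")
        if any(h < 0 for h in self.hours.values()):
            raise ValueError("hours must be >= 0")
        total = sum(self.hours.values())
        if abs(total - 24.0) > 0.01:
            raise ValueError(f"daily hours sum to {total}, expected 24 +/- 0.01")
        missing = set(self.hours) - set(self.eec_map)
        if missing:
            raise ValueError(f"eec_map missing locations: {sorted(missing)}")


@dataclass(frozen=True)
class AgeGroupExposure:
    """Annual exposure for one age group, split by location.

    ``per_location`` and ``total`` are unrounded h Bq/m3 of EEC;
    ``contribution`` gives percentages with outdoors and vehicle merged
    (reporting convention: both are assigned outdoor air).
    """

    age_group: str
    per_location: Mapping[str, float]
    total: float
    contribution: Mapping[str, float]


def age_group_exposure(pattern: TimeActivityPattern) -> AgeGroupExposure:
    """Annual per-location exposures, their total, and percent contributions.

    The total is the sum of unrounded per-location values; rounding is a
    display concern.  Contributions merge outdoors and in-vehicle.
    """
    per_loc = {
        loc: annual_exposure(pattern.hours[loc], pattern.eec_map[loc])
        for loc in LOCATIONS
    }
    total = sum(per_loc.values())
    if total > 0:
        contribution = {
            "home": per_loc["home"] / total * 100.0,
            "indoors_away": per_loc["indoors_away"] / total * 100.0,
            "outdoors_vehicle": (per_loc["outdoors"] + per_loc["vehicle"])
            / total
            * 100.0,
        }
    else:
        contribution = {}
    return AgeGroupExposure(pattern.age_group, per_loc, total, contribution)


def age_group_for_age(age: int) -> str:
    """Age group containing year-of-life ``age`` (0..109)."""
    for group, (lo, hi) in AGE_GROUP_SPANS.items():
        if lo <= age <= hi:
            return group
    raise ValueError(f"age {age} outside the 0..{LIFESPAN - 1} lifespan")


@dataclass(frozen=True)
class ExposureHistory:
    """Per-year-of-life, per-location exposure in WLM over a 110-y lifespan.

    ``wlm`` has shape (110, n_locations); row i is year of life i (age i at
    the start of the year), columns follow :data:`LOCATIONS`.
    """

    wlm: np.ndarray

    def __post_init__(self) -> None:
        if self.wlm.shape != (LIFESPAN, len(LOCATIONS)):
            raise ValueError(
                f"history must have shape {(LIFESPAN, len(LOCATIONS))}, "
                f"got {self.wlm.shape}"
            )
        if np.any(self.wlm < 0):
            raise ValueError("exposure history entries must be >= 0")

    @property
    def total_per_year(self) -> np.ndarray:
        """Total WLM per year of life, shape (110,)."""
        return self.wlm.sum(axis=1)


def build_lifetime_history(
    patterns: Mapping[str, TimeActivityPattern] | Iterable[TimeActivityPattern],
    locations: Sequence[str] | str = "all",
) -> ExposureHistory:
    """Lifetime exposure history from the six age-group patterns.

    Each year of life receives the annual per-location WLM of the age group
    containing it.  ``locations`` restricts the history to a subset of
    microenvironments (all others zeroed), which is how single-location
    attribution runs are built.
    """
    if not isinstance(patterns, Mapping):
        patterns = {p.age_group: p for p in patterns}
    missing = set(AGE_GROUPS) - set(patterns)
    if missing:
        raise ValueError(f"missing age groups: {sorted(missing)}")
    if locations == "all":
        keep = set(LOCATIONS)
    else:
        keep = set(locations)
        unknown = keep - set(LOCATIONS)
        if unknown:
            raise ValueError(f"unknown locations: {sorted(unknown)}")

    wlm = np.zeros((LIFESPAN, len(LOCATIONS)))
    for group, (lo, hi) in AGE_GROUP_SPANS.items():
        p = patterns[group]
        row = [
            to_wlm(annual_exposure(p.hours[loc], p.eec_map[loc]))
            if loc in keep
            else 0.0
            for loc in LOCATIONS
        ]
        wlm[lo : hi + 1, :] = row
    return ExposureHistory(wlm)


def exposure_windows(
    history: ExposureHistory, a: int, lag: int = LAG_YEARS
) -> tuple[float, float, float]:
    """Cumulative WLM in the three time-since-exposure windows at age ``a``.

    Returns ``(W_5_14, W_15_24, W_25plus)``: exposure received 5-14, 15-24
    and >= 25 years before attained age ``a``, i.e. at ages
    [a-14, a-5], [a-24, a-15] and [0, a-25], clipped to lived years.
    Exposure within the last ``lag`` years is never counted.
    """
    if not 0 <= a <= LIFESPAN:
        raise ValueError(f"attained age must be in [0, {LIFESPAN}], got {a}")
    total = history.total_per_year

    def window(lo_age: int, hi_age: int) -> float:
        lo = max(lo_age, 0)
        hi = min(hi_age, a - lag, LIFESPAN - 1)
        if hi < lo:
            return 0.0
        return float(total[lo : hi + 1].sum())

    w_5_14 = window(a - 14, a - 5)
    w_15_24 = window(a - 24, a - 15)
    w_25plus = window(0, a - 25)
    return (w_5_14, w_15_24, w_25plus)


def load_time_activity(path: str | Path) -> dict[str, TimeActivityPattern]:
    """Read time-activity patterns from CSV (``age_group,location,hours,eec``)."""
    df = pd.read_csv(path)
    required = {"age_group", "location", "hours", "eec"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"time-activity CSV {path} is missing columns: {sorted(missing)}"
        )
    patterns = {}
    for group, sub in df.groupby("age_group", sort=False):
        hours = dict(zip(sub["location"], sub["hours"].astype(float)))
        eec_map = dict(zip(sub["location"], sub["eec"].astype(float)))
        patterns[str(group)] = TimeActivityPattern(str(group), hours, eec_map)
    return patterns


def table2_patterns() -> dict[str, TimeActivityPattern]:
    """The packaged Canadian time-activity / EEC table."""
    return load_time_activity(Path(__file__).parent / "data" / "table2_time_activity.csv")
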