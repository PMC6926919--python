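"""Excess relative risk and life-table lifetime lung-cancer risk.

The excess relative risk (ERR) of lung-cancer death at attained age ``a``
follows the BEIR-VI / EPA exposure-age-concentration form

    e(a) = beta * (W_5-14 + theta_15-24 * W_15-24 + theta_25+ * W_25+) * phi_age(a)

where the W's are cumulative working-level-month (WLM) exposures in the
three time-since-exposure windows (exposure in the most recent 5 years is
not biologically effective), beta is the ERR per WLM, the thetas discount
older exposure, and phi_age is a non-increasing attained-age effect
modifier.

Lifetime absolute risk uses the BEIR-IV double-decrement life table: with
h_i the baseline lung-cancer mortality rate and h*_i the all-cause rate at
age i, the exposed total hazard in year i is H_i = h*_i + h_i e_i, and

    R_e(a) = sum_{i=1}^{a}  [h_i (1 + e_i) / H_i]
             * prod_{k<i} exp(-H_k) * [1 - exp(-H_i)] ,

the probability of dying of lung cancer by age a.  A lifespan of 110 years
is assumed; the lifetime risk is R_e(110).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import (
    LIFESPAN,
    LOCATIONS,
    WLM_H_BQM3,
    ExposureHistory,
    TimeActivityPattern,
    build_lifetime_history,
    exposure_windows,
)

__all__ = [
    "RiskParams",
    "MortalityTable",
    "LifetimeRiskResult",
    "err",
    "err_series",
    "lifetime_risk",
    "baseline_risk",
    "relative_risk",
    "attribute_by_location",
    "load_mortality",
]


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the windowed-ERR risk model.

    Defaults are the published exposure-age-concentration parameterisation:
    beta = 0.0634 ERR/WLM with window weights 0.78 (15-24 y) and 0.51
    (25+ y).  The attained-age modifier phi_age is piecewise constant on
    [0, break_1), [break_1, break_2), ...; the default categories are
    <55: 1.00, 55-64: 0.57, 65-74: 0.29, 75+: 0.09.
    """

    beta: float = 0.0634
    theta_15_24: float = 0.78
    theta_25plus: float = 0.51
    phi_breaks: tuple[float, ...] = (55.0, 65.0, 75.0)
    phi_values: tuple[float, ...] = (1.00, 0.57, 0.29, 0.09)
    lag: int = 5
    wlm_h_bqm3: float = WLM_H_BQM3

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        for name, theta in [
            ("theta_15_24", self.theta_15_24),
            ("theta_25plus", self.theta_25plus),
        ]:
            if not 0 < theta <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {theta}")
        if len(self.phi_values) != len(self.phi_breaks) + 1:
            raise ValueError("phi_values must have one more entry than phi_breaks")
        if list(self.phi_breaks) != sorted(self.phi_breaks):
            raise ValueError("phi_breaks must be increasing")
        vals = list(self.phi_values)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("phi values must lie in [0, 1]")
        if any(b > a for a, b in zip(vals, vals[1:])):
            raise ValueError("phi_age must be non-increasing with attained age")

    def phi(self, a: float) -> float:
        """Attained-age effect modifier phi_age(a)."""
        return float(self.phi_values[int(np.searchsorted(self.phi_breaks, a, side="right"))])


@dataclass(frozen=True)
class MortalityTable:
    """Age-specific lung-cancer and all-cause mortality rates for one sex.

    ``h_lung[i]`` and ``h_all[i]`` are the rates (1/y) for life-table year
    i+1, i.e. ages 1..110.  All-cause rates include baseline lung cancer.
    """

    sex: str
    h_lung: np.ndarray
    h_all: np.ndarray

    def __post_init__(self) -> None:
        if self.h_lung.shape != (LIFESPAN,) or self.h_all.shape != (LIFESPAN,):
            raise ValueError(f"rates must cover ages 1..{LIFESPAN}")
        if np.any(self.h_lung < 0):
            raise ValueError("lung-cancer rates must be >= 0")
        if np.any(self.h_all <= 0):
            raise ValueError("all-cause rates must be > 0 at every age")
        if np.any(self.h_lung > self.h_all):
            raise ValueError("lung-cancer rate exceeds all-cause rate")


@dataclass(frozen=True)
class LifetimeRiskResult:
    """Cumulative absolute lung-cancer risk by attained age.

    ``cumulative[a-1]`` is R(a) for a = 1..110; ``lifetime`` is R(110).
    ``yearly`` holds each year's unconditional lung-cancer death
    probability, and ``survival`` the probability of being alive at the
    start of each year.
    """

    cumulative: np.ndarray
    yearly: np.ndarray
    survival: np.ndarray
    lifetime: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lifetime", float(self.cumulative[-1]))

    def risk_at(self, a: int) -> float:
        """Cumulative risk R(a) at attained age a (1..110)."""
        if not 1 <= a <= LIFESPAN:
            raise ValueError(f"attained age must be in [1, {LIFESPAN}], got {a}")
        return float(self.cumulative[a - 1])


def err(a: int, history: ExposureHistory, params: RiskParams) -> float:
    """Excess relative risk e(a) at attained age ``a`` for ``history``."""
    w_5_14, w_15_24, w_25plus = exposure_windows(history, a, lag=params.lag)
    weighted = w_5_14 + params.theta_15_24 * w_15_24 + params.theta_25plus * w_25plus
    return params.beta * weighted * params.phi(a)


def err_series(history: ExposureHistory, params: RiskParams) -> np.ndarray:
    """e_i for life-table years i = 1..110 (attained age = i)."""
    return np.array([err(a, history, params) for a in range(1, LIFESPAN + 1)])


def lifetime_risk(
    mortality: MortalityTable,
    err_by_year: np.ndarray | Sequence[float],
    final_bracket: str = "total_hazard",
) -> LifetimeRiskResult:
    """Absolute lung-cancer risk by attained age from the life-table sum.

    ``err_by_year`` gives e_i for i = 1..110.  ``final_bracket`` selects the
    hazard used in the yearly death probability: ``"total_hazard"`` (the
    BEIR-IV construction, h* + h e) or ``"printed"`` (h* - h e, retained
    only for comparison; it makes exposure reduce total deaths).
    """
    e = np.asarray(err_by_year, dtype=float)
    if e.shape != (LIFESPAN,):
        raise ValueError(f"err series must cover ages 1..{LIFESPAN}")
    if np.any(e < 0):
        raise ValueError("excess relative risk must be >= 0")
    if final_bracket not in ("total_hazard", "printed"):
        raise ValueError(f"unknown final_bracket {final_bracket!r}")

    h, h_star = mortality.h_lung, mortality.h_all
    total_hazard = h_star + h * e
    death_hazard = total_hazard if final_bracket == "total_hazard" else h_star - h * e

    # P(alive at start of year i); survival decrements use the total hazard.
    survival = np.ones(LIFESPAN)
    survival[1:] = np.exp(-np.cumsum(total_hazard[:-1]))

    with np.errstate(invalid="ignore", divide="ignore"):
        cause_fraction = np.where(total_hazard > 0, h * (1 + e) / total_hazard, 0.0)
    yearly = cause_fraction * survival * (1.0 - np.exp(-death_hazard))
    return LifetimeRiskResult(
        cumulative=np.cumsum(yearly), yearly=yearly, survival=survival
    )


def baseline_risk(mortality: MortalityTable) -> LifetimeRiskResult:
    """Lifetime risk with zero radon excess (e_i = 0 for all i)."""
    return lifetime_risk(mortality, np.zeros(LIFESPAN))


def relative_risk(
    exposed: LifetimeRiskResult, baseline: LifetimeRiskResult
) -> np.ndarray:
    """RR(a) = R_e(a) / R_0(a) for a = 1..110; NaN where R_0(a) = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.where(
            baseline.cumulative > 0, exposed.cumulative / baseline.cumulative, np.nan
        )
    return rr


def attribute_by_location(
    patterns: Mapping[str, TimeActivityPattern],
    mortality: MortalityTable,
    params: RiskParams,
) -> dict[str, float]:
    """Percent of lifetime excess risk attributable to each microenvironment.

    For each location, a single-location exposure history is run through
    the life table; its share is (R_loc - R_0) / (R_all - R_0) * 100 at age
    110.  Because the ERR enters the life table nonlinearly, shares need
    not sum exactly to 100 (the deviation is small at environmental
    exposure levels).
    """
    r0 = baseline_risk(mortality).lifetime
    all_hist = build_lifetime_history(patterns, "all")
    r_all = lifetime_risk(mortality, err_series(all_hist, params)).lifetime
    excess_all = r_all - r0
    if excess_all <= 0:
        raise ValueError("no excess risk at any location; attribution undefined")
    shares = {}
    for loc in LOCATIONS:
        hist = build_lifetime_history(patterns, [loc])
        r_loc = lifetime_risk(mortality, err_series(hist, params)).lifetime
        shares[loc] = (r_loc - r0) / excess_all * 100.0
    return shares


def load_mortality(path: str | Path) -> dict[str, MortalityTable]:
    """Read per-sex mortality tables from CSV (``sex,age,h_lung,h_all``)."""
    df = pd.read_csv(path)
    required = {"sex", "age", "h_lung", "h_all"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mortality CSV {path} is missing columns: {sorted(missing)}")
    tables = {}
    for sex, sub in df.groupby("sex", sort=False):
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy()
        if not np.array_equal(ages, np.arange(1, LIFESPAN + 1)):
            raise ValueError(f"mortality table for sex {sex!r} must cover ages 1..110")
        tables[str(sex)] = MortalityTable(
            sex=str(sex),
            h_lung=sub["h_lung"].to_numpy(dtype=float),
            h_all=sub["h_all"].to_numpy(dtype=float),
        )
    return tables
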