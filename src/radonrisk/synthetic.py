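"""Synthetic inputs and the Monte-Carlo life-table oracle.

The risk pipeline needs sex- and age-specific all-cause and lung-cancer
mortality rates, which come from national vital statistics and are not
shipped here.  :func:`make_mortality_table` generates a synthetic table
with the structure such rates have: a Gompertz-Makeham all-cause hazard,
and a lung-cancer hazard that is zero below a sex-specific onset age
(reflecting that lung-cancer deaths are essentially unobserved below age
~10 in males and ~20 in females), rises steeply after mid-life, and never
exceeds the all-cause hazard.

:func:`make_survey_table` draws regional radon surveys from lognormal
concentration distributions, the standard model for indoor radon.

:func:`cohort_simulator` is an independent stochastic check on the
analytic life-table sum: it follows a closed cohort year by year, killing
members with probability 1 - exp(-(h* + h e)) and attributing each death
to lung cancer with probability h(1+e)/(h* + h e).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exposure import LIFESPAN
from .risk import MortalityTable
from .survey import SurveyRecord

__all__ = [
    "SyntheticConfig",
    "make_survey_table",
    "make_mortality_table",
    "cohort_simulator",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic-data generators.

    Radon distributions are lognormal with geometric mean ``gm`` (Bq/m3)
    and geometric standard deviation ``gsd`` per building class; defaults
    are in the range reported by Canadian surveys.  The all-cause hazard is
    Gompertz-Makeham ``makeham + gompertz_a * exp(gompertz_b * age)``; the
    lung-cancer hazard is a logistic-in-age fraction of the all-cause
    hazard, zero below the sex-specific onset age.  Defaults were fixed
    once, by checking with the analytic life table that the baseline
    lifetime lung-cancer risk lands in the realistic 0.03-0.10 range, and
    are part of the packaged study conditions.
    """

    seed: int = 0
    n_regions: int = 13
    population_range: tuple[int, int] = (8_000, 1_400_000)
    n_tested_range: tuple[int, int] = (10, 2400)
    radon_gm: Mapping[str, float] = field(
        default_factory=lambda: {"home": 90.0, "school": 45.0, "public": 28.0}
    )
    radon_gsd: Mapping[str, float] = field(
        default_factory=lambda: {"home": 2.2, "school": 2.0, "public": 2.0}
    )
    # all-cause Gompertz-Makeham hazard (1/y)
    gompertz_a: float = 3.0e-5
    gompertz_b: float = 0.095
    makeham: float = 5.0e-4
    # lung-cancer hazard: logistic fraction of all-cause, higher in males
    lung_frac_max: Mapping[str, float] = field(
        default_factory=lambda: {"male": 0.095, "female": 0.072}
    )
    lung_mid_age: float = 62.0
    lung_width: float = 7.0
    onset_age: Mapping[str, int] = field(
        default_factory=lambda: {"male": 10, "female": 20}
    )
    cohort_size: int = 1_000_000

    def __post_init__(self) -> None:
        for cls, gm in self.radon_gm.items():
            if gm <= 0:
                raise ValueError(f"geometric mean for {cls!r} must be > 0")
        for cls, gsd in self.radon_gsd.items():
            if gsd < 1:
                raise ValueError(f"geometric SD for {cls!r} must be >= 1")
        for sex, frac in self.lung_frac_max.items():
            if not 0 < frac < 1:
                raise ValueError(f"lung_frac_max for {sex!r} must be in (0, 1)")


def make_survey_table(cfg: SyntheticConfig) -> list[SurveyRecord]:
    """Draw a regional radon survey compilation.

    For each region and building class, ``n_tested`` concentrations are
    drawn from the class lognormal and summarised by their arithmetic mean
    and SD, mirroring how real surveys are reported.  Pure function of the
    config (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[SurveyRecord] = []
    lo_p, hi_p = cfg.population_range
    lo_n, hi_n = cfg.n_tested_range
    for r in range(cfg.n_regions):
        population = int(rng.integers(lo_p, hi_p + 1))
        for cls in cfg.radon_gm:
            n = int(rng.integers(lo_n, hi_n + 1))
            sigma = np.log(cfg.radon_gsd[cls])
            if sigma == 0:
                draws = np.full(n, cfg.radon_gm[cls])
            else:
                draws = rng.lognormal(np.log(cfg.radon_gm[cls]), sigma, size=n)
            records.append(
                SurveyRecord(
                    region=f"region_{r:02d}",
                    population=population,
                    building_function=cls,
                    n_tested=n,
                    mean_rn=float(draws.mean()),
                    sd=float(draws.std(ddof=1)) if n > 1 else None,
                    range_low=float(draws.min()),
                    range_high=float(draws.max()),
                )
            )
    return records


def make_mortality_table(cfg: SyntheticConfig, sex: str) -> MortalityTable:
    """Synthetic mortality table for ``sex`` (deterministic given cfg).

    All-cause: Gompertz-Makeham.  Lung cancer: zero below the sex-specific
    onset age, then a logistic-in-age fraction of the all-cause hazard
    rising towards ``lung_frac_max`` around ``lung_mid_age``.
    """
    if sex not in cfg.onset_age:
        raise ValueError(f"no onset age configured for sex {sex!r}")
    ages = np.arange(1, LIFESPAN + 1, dtype=float)
    h_all = cfg.makeham + cfg.gompertz_a * np.exp(cfg.gompertz_b * ages)
    frac_max = cfg.lung_frac_max[sex]
    frac = frac_max / (1.0 + np.exp(-(ages - cfg.lung_mid_age) / cfg.lung_width))
    frac[ages < cfg.onset_age[sex]] = 0.0
    return MortalityTable(sex=sex, h_lung=frac * h_all, h_all=h_all)


def cohort_simulator(
    mortality: MortalityTable,
    err_by_year: np.ndarray,
    n: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo estimate of lifetime lung-cancer risk with binomial SE.

    Follows a closed cohort of ``n`` individuals through ages 1..110.  In
    year i each survivor dies with probability 1 - exp(-(h*_i + h_i e_i));
    each death is lung cancer with probability h_i (1+e_i)/(h*_i + h_i e_i).
    Cohort members are exchangeable, so the per-year death and
    cause-of-death counts are drawn as Binomials on the aggregate — the
    estimator's distribution is identical to per-individual simulation.

    Returns ``(estimated risk, standard error)``.
    """
    e = np.asarray(err_by_year, dtype=float)
    if e.shape != (LIFESPAN,):
        raise ValueError(f"err series must cover ages 1..{LIFESPAN}")
    rng = np.random.default_rng(seed)
    h, h_star = mortality.h_lung, mortality.h_all
    total_hazard = h_star + h * e
    p_death = 1.0 - np.exp(-total_hazard)
    p_lung_given_death = h * (1.0 + e) / total_hazard

    alive = n
    lung_deaths = 0
    for i in range(LIFESPAN):
        if alive == 0:
            break
        deaths = int(rng.binomial(alive, p_death[i]))
        if deaths and p_lung_given_death[i] > 0:
            lung_deaths += int(rng.binomial(deaths, p_lung_given_death[i]))
        alive -= deaths
    p_hat = lung_deaths / n
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return (p_hat, se)
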