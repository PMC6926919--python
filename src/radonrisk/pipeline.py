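"""End-to-end assessment pipeline.

Ties the modules together: survey aggregation, exposure tables, lifetime
risk and relative risk per sex, and per-location attribution.  The
:class:`PipelineConfig` points at the input CSVs (packaged fixtures by
default, a synthetic mortality table when none is supplied) and carries the
risk-model parameters; :func:`run_full_pipeline` writes every output table
under the configured directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import exposure, risk, survey, synthetic
from .exposure import LOCATIONS, round_half_up

logger = logging.getLogger("radonrisk")

__all__ = [
    "PipelineConfig",
    "load_config",
    "risk_params_from_config",
    "national_summary_frame",
    "exposure_table_frame",
    "exposure_totals_frame",
    "risk_series_frame",
    "attribution_frame",
    "run_full_pipeline",
]

_DATA = Path(__file__).parent / "data"
DEFAULT_CONFIG_PATH = _DATA / "default_config.yaml"


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the default YAML config, overlaid with ``path`` if given."""
    with open(DEFAULT_CONFIG_PATH) as fh:
        cfg = yaml.safe_load(fh)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def risk_params_from_config(cfg: Mapping[str, Any]) -> risk.RiskParams:
    """Build :class:`~radonrisk.risk.RiskParams` from a config mapping."""
    r = cfg.get("risk", {})
    return risk.RiskParams(
        beta=float(r.get("beta", 0.0634)),
        theta_15_24=float(r.get("theta_15_24", 0.78)),
        theta_25plus=float(r.get("theta_25plus", 0.51)),
        phi_breaks=tuple(float(b) for b in r.get("phi_breaks", (55, 65, 75))),
        phi_values=tuple(float(v) for v in r.get("phi_values", (1.0, 0.57, 0.29, 0.09))),
        lag=int(r.get("lag", 5)),
        wlm_h_bqm3=float(cfg.get("wlm_h_bqm3", exposure.WLM_H_BQM3)),
    )


@dataclass
class PipelineConfig:
    """Paths and parameters for a full assessment run."""

    surveys: Path = _DATA / "table1_surveys.csv"
    time_activity: Path = _DATA / "table2_time_activity.csv"
    mortality: Path | None = None  # None -> packaged synthetic table
    outdir: Path = Path("results")
    params: risk.RiskParams = field(default_factory=risk.RiskParams)
    synthetic_cfg: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    log_level: str = "INFO"


def national_summary_frame(records: list[survey.SurveyRecord]) -> pd.DataFrame:
    """National per-class counts and weighted means as a tidy frame."""
    summ = survey.national_summary(records)
    rows = [
        {
            "building_class": cls,
            "n_total": int(v["n_total"]),
            "weighted_mean": v["weighted_mean"],
            "weighted_mean_rounded": int(round_half_up(v["weighted_mean"])),
        }
        for cls, v in summ.items()
    ]
    return pd.DataFrame(rows)


def exposure_table_frame(
    patterns: Mapping[str, exposure.TimeActivityPattern],
) -> pd.DataFrame:
    """Per-location annual exposures by age group (display-rounded)."""
    rows = []
    for group in exposure.AGE_GROUPS:
        p = patterns[group]
        for loc in LOCATIONS:
            raw = exposure.annual_exposure(p.hours[loc], p.eec_map[loc])
            rows.append(
                {
                    "age_group": group,
                    "location": loc,
                    "hours": p.hours[loc],
                    "eec": p.eec_map[loc],
                    "annual_exposure": int(round_half_up(raw)),
                }
            )
    return pd.DataFrame(rows)


def exposure_totals_frame(
    patterns: Mapping[str, exposure.TimeActivityPattern],
) -> pd.DataFrame:
    """Total annual exposure and percent contributions by age group."""
    rows = []
    for group in exposure.AGE_GROUPS:
        agg = exposure.age_group_exposure(patterns[group])
        rows.append(
            {
                "age_group": group,
                "total_annual_exposure": int(round_half_up(agg.total)),
                "pct_home": round_half_up(agg.contribution["home"], 1),
                "pct_indoors_away": round_half_up(agg.contribution["indoors_away"], 1),
                "pct_outdoors_vehicle": round_half_up(
                    agg.contribution["outdoors_vehicle"], 1
                ),
            }
        )
    return pd.DataFrame(rows)


def risk_series_frame(
    mortality: risk.MortalityTable,
    patterns: Mapping[str, exposure.TimeActivityPattern],
    params: risk.RiskParams,
    locations: Any = "all",
) -> pd.DataFrame:
    """Cumulative absolute and relative risk by attained age for one sex."""
    hist = exposure.build_lifetime_history(patterns, locations)
    exposed = risk.lifetime_risk(mortality, risk.err_series(hist, params))
    base = risk.baseline_risk(mortality)
    rr = risk.relative_risk(exposed, base)
    return pd.DataFrame(
        {
            "age": np.arange(1, exposure.LIFESPAN + 1),
            "R_e": exposed.cumulative,
            "R_0": base.cumulative,
            "RR": rr,
        }
    )


def attribution_frame(
    mortality_by_sex: Mapping[str, risk.MortalityTable],
    patterns: Mapping[str, exposure.TimeActivityPattern],
    params: risk.RiskParams,
) -> pd.DataFrame:
    """Per-location share of lifetime excess risk, one row per sex/location."""
    rows = []
    for sex, table in mortality_by_sex.items():
        shares = risk.attribute_by_location(patterns, table, params)
        for loc, pct in shares.items():
            rows.append({"sex": sex, "location": loc, "pct_excess_risk": pct})
    return pd.DataFrame(rows)


def _load_mortality(cfg: PipelineConfig) -> dict[str, risk.MortalityTable]:
    if cfg.mortality is not None:
        logger.info("loading mortality rates from %s", cfg.mortality)
        return risk.load_mortality(cfg.mortality)
    logger.info("no mortality table supplied; using the packaged synthetic table")
    return {
        sex: synthetic.make_mortality_table(cfg.synthetic_cfg, sex)
        for sex in cfg.synthetic_cfg.onset_age
    }


def run_full_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run aggregation, exposure, risk and attribution; write CSVs.

    Returns the output tables keyed by name; each is also written to
    ``cfg.outdir/<name>.csv``.
    """
    logging.basicConfig(level=cfg.log_level)
    logger.info(
        "risk params: beta=%g theta=(%g, %g) phi=%s lag=%d",
        cfg.params.beta,
        cfg.params.theta_15_24,
        cfg.params.theta_25plus,
        dict(zip(("<break",) * len(cfg.params.phi_values), cfg.params.phi_values)),
        cfg.params.lag,
    )
    records = survey.load_surveys(cfg.surveys)
    patterns = exposure.load_time_activity(cfg.time_activity)
    mortality = _load_mortality(cfg)

    out: dict[str, pd.DataFrame] = {
        "national_summary": national_summary_frame(records),
        "exposure_table": exposure_table_frame(patterns),
        "exposure_totals": exposure_totals_frame(patterns),
        "attribution": attribution_frame(mortality, patterns, cfg.params),
    }
    for sex, table in mortality.items():
        out[f"risk_series_{sex}"] = risk_series_frame(table, patterns, cfg.params)

    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for name, frame in out.items():
        path = Path(cfg.outdir) / f"{name}.csv"
        frame.to_csv(path, index=False)
        logger.info("wrote %s (%d rows)", path, len(frame))
    return out
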