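# radonrisk

Radon-progeny exposure assessment across indoor microenvironments, and the
lifetime lung-cancer risk it implies.

Radon (²²²Rn) seeping from soil accumulates indoors; its short-lived decay
products deliver most of the radiation dose to the lung and are the second
leading cause of lung cancer after smoking. Because people move between
environments with very different radon levels — dwellings, schools, public
buildings and workplaces, vehicles, outdoor air — assessing the population
risk takes three linked steps, each implemented here as a tested library
module:

1. **Survey aggregation** (`radonrisk.survey`): regional radon surveys
   (arithmetic-mean concentration, number of places tested) are pooled
   within region by measurement count and combined across regions by census
   population, yielding national per-class means. The packaged Canadian
   compilation gives 119 Bq/m³ in homes, 61 in schools, 38 in public
   buildings.
2. **Exposure model** (`radonrisk.exposure`): concentrations become
   progeny exposure via the equilibrium-equivalent concentration
   EEC = radon × F_eq (F_eq = 0.6 in homes and outdoors, 0.4 in schools and
   public buildings), combined with age-group time-activity patterns into
   annual exposures (h·Bq/m³) and lifetime histories in working level
   months, 1 WLM = 6.37 × 10⁵ h·Bq/m³ EEC.
3. **Risk model** (`radonrisk.risk`): the excess relative risk at attained
   age *a* uses the BEIR-VI/EPA exposure-age-concentration form

       e(a) = β (W₅₋₁₄ + 0.78 W₁₅₋₂₄ + 0.51 W₂₅₊) Φ_age(a),   β = 0.0634 /WLM

   with W the cumulative WLM in the three time-since-exposure windows
   (the most recent 5 years carry no risk) and Φ_age non-increasing in age.
   Lifetime absolute risk follows the BEIR-IV double-decrement life table

       R_e = Σᵢ₌₁¹¹⁰ [hᵢ(1+eᵢ)/(hᵢ*+hᵢeᵢ)] ∏ₖ₌₁ⁱ⁻¹ exp(−(hₖ*+hₖeₖ)) [1−exp(−(hᵢ*+hᵢeᵢ))]

   over a 110-year lifespan, with hᵢ and hᵢ* the lung-cancer and all-cause
   mortality rates. Per-location attribution compares single-location
   histories against the all-location run.

National vital-statistics mortality tables are inputs, not shipped;
`radonrisk.synthetic` generates a structurally faithful synthetic table
(sex-specific onset ages, Gompertz-Makeham all-cause hazard) plus a
Monte-Carlo cohort simulator that independently verifies the life-table
sum. See `docs/methods.md` for model details and caveats.

## Worked example

```python
from radonrisk import (RiskParams, attribute_by_location, baseline_risk,
                       build_lifetime_history, err_series, lifetime_risk,
                       national_summary, table1_surveys, table2_patterns)
from radonrisk.synthetic import SyntheticConfig, make_mortality_table

summary = national_summary(table1_surveys())
print({c: round(v["weighted_mean"]) for c, v in summary.items()})
# {'home': 119, 'school': 61, 'public': 38}

patterns = table2_patterns()
mortality = make_mortality_table(SyntheticConfig(), "female")
history = build_lifetime_history(patterns)
exposed = lifetime_risk(mortality, err_series(history, RiskParams()))
base = baseline_risk(mortality)
print(round(exposed.lifetime, 4), round(base.lifetime, 4))
# 0.075 0.0582   — lifetime risk with and without radon exposure
shares = attribute_by_location(patterns, mortality, RiskParams())
print(round(shares["home"], 1))
# 92.5   — percent of the excess risk due to exposure at home
```

A lifetime of exposure at average Canadian levels raises this synthetic
cohort's lifetime lung-cancer risk from 0.0582 to 0.0750 (relative risk
1.29 at age 110), and 92.5% of that excess comes from time spent indoors
at home — which is why residential remediation dominates radon policy.

The numbered scripts under `analysis/` run the same steps as narrative
drivers (`python analysis/01_aggregate_surveys.py`, …) and write their
tables under `results/`. A `radonrisk` CLI exposes the pipeline
(`radonrisk aggregate`, `exposure-table`, `history`, `risk`, `attribute`,
`simulate`, `run`).

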