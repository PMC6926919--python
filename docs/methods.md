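# Methods

## Survey aggregation

Each survey record is one building function in one region: the number of
places tested and the arithmetic-mean radon concentration (Bq/m³), with
optional SD and range. Aggregation is two-stage:

* **Within region**, multiple surveys of the same class are pooled with
  weights proportional to the number of places tested — the arithmetic mean
  the concatenated samples would have. Weighting by measurement count (not
  population) is the scheme that reproduces the published national row from
  the packaged compilation for all three classes; a simple average of
  survey means does not.
* **Across regions**, pooled means are weighted by census population.
  Regions without data for a class are omitted from that class entirely
  (no data ≠ zero concentration).

Civic, provincial and federal buildings all map to the *public* class.
Senior residences are kept out of the public class and counted as
dwellings: that is the only assignment under which the per-class totals of
the packaged fixture match the published counts (7866 homes / 1132 schools
/ 1668 public buildings), and it is defensible on substance — they are
residential buildings. The class map is an argument, so either convention
is one dictionary away.

Weighted means are carried at full precision and rounded only for display.
Display rounding is half-away-from-zero throughout (the convention the
published tables use: 0.95 h × 6 Bq/m³ × 365 d = 2080.5 → 2081), with a
1e-9 relative epsilon so that values which are exact decimal ties but sit
one ulp below them in binary still round up.

## Exposure model

Progeny exposure is driven by the equilibrium-equivalent concentration
EEC = radon × F_eq. Defaults: F_eq = 0.6 for homes and outdoor air,
0.4 for schools and public buildings; outdoor radon 10 Bq/m³ (worldwide
average), giving location EECs 71.4 / 24.4 / 15.2 / 6 Bq/m³ for home /
school / public / outdoor-and-vehicle. Vehicles are assigned outdoor air.

Six age groups partition the 110-year lifespan: <1, 1–4, 5–11, 12–19,
20–59, 60+. Each has a 24-hour time budget over four microenvironments
(home, indoors away from home, outdoors, vehicle) and an age-specific EEC
for "indoors away": public buildings for infants, homes for young children
(daycare is mostly home-based), schools for ages 5–19, workplaces/public
buildings for adults and seniors. Annual exposure per location is
hours/day × EEC × 365; a 365-day year is the convention that reproduces
the published annual-exposure cells exactly. Totals are summed unrounded
and rounded once (summing rounded addends gives a different last digit for
the 1–4 group). Contribution percentages merge outdoors and vehicle.

Two packaged EEC values deserve a note. The adolescent "indoors away" EEC
is 24.2 Bq/m³ rather than the school value 24.4; 24.2 is what the source
table prints and what reproduces its annual-exposure cell (4.98 × 24.2 ×
365 = 43 988), so it is kept, possibly propagating a typo — the CSV fixture
is the single place to change it. Conversion to working level months uses
1 WLM = 6.37 × 10⁵ h·Bq/m³ EEC.

A lifetime exposure history assigns each year of life its age group's
annual per-location WLM. Restricting the history to a location subset
zeroes the rest; single-location histories drive the attribution.

### Time-since-exposure windows

At attained age *a*, W₅₋₁₄ sums exposure over ages [a−14, a−5], W₁₅₋₂₄
over [a−24, a−15], W₂₅₊ over [0, a−25], all clipped to lived years; the 5
most recent years never count (biological lag). Windows are computed on
whole years of age — no sub-annual convention is defined, so year-of-life
granularity is the natural resolution of the life table. The three windows
exactly partition the exposure received 5+ years before *a* (a property
test asserts this for all ages).

## Risk model

Excess relative risk: e(a) = β (W₅₋₁₄ + θ₁₅₋₂₄ W₁₅₋₂₄ + θ₂₅₊ W₂₅₊) Φ_age(a)
with defaults β = 0.0634 per WLM, θ₁₅₋₂₄ = 0.78, θ₂₅₊ = 0.51 — the BEIR-VI
exposure-age-concentration parameterisation as adjusted by the EPA. The
attained-age modifier Φ_age is piecewise constant and validated
non-increasing; the source assessment does not print its values, so the
default uses the BEIR-VI exposure-age-concentration categories (<55: 1.00,
55–64: 0.57, 65–74: 0.29, 75+: 0.09) — the sub-model the θ weights belong
to. Any piecewise-constant modifier can be supplied via `RiskParams` or
the YAML config.

Lifetime risk is the BEIR-IV double-decrement life-table sum over ages
1..110 (e_i is evaluated at attained age i; exposure year 0 feeds the
first life-table year). Within year i the total hazard is H_i = h*_i +
h_i e_i — h*_i is all-cause mortality *including* baseline lung cancer, so
the radon excess adds only h_i e_i — and the year's lung-cancer death
probability is the cause fraction h_i(1+e_i)/H_i times the probability of
surviving to i and dying within it. The final bracket uses the total
hazard 1−exp(−H_i): the subtracted-hazard variant seen in some printed
renderings of the formula would make radon exposure *reduce* total deaths
and is retained only behind `final_bracket="printed"` for comparison.
Terms with H_i = 0 contribute zero; tables with h*_i = 0 anywhere are
rejected at construction.

Baseline risk R₀ is the same sum with e ≡ 0; RR(a) = R_e(a)/R₀(a) is
reported as missing where R₀(a) = 0 (before the sex-specific onset age).
All risk computations are per sex; combining sexes is an explicit
population-weighted average by the caller (the acceptance script uses an
unweighted mean of the two sexes).

### Attribution

Location shares are (R_loc − R₀)/(R_all − R₀) × 100 at age 110, one
single-location history per microenvironment. Because e enters the life
table nonlinearly, shares do not sum to exactly 100; at survey-scale
exposures the packaged run gives 92.5 + 6.6 + 0.7 + 0.6 ≈ 100.3 (within
the <1-percentage-point regime), and in the β→0 limit the shares converge
to the linear exposure-weighted decomposition (tested).

## Synthetic data

`make_mortality_table` emulates the *structure* of national vital
statistics without shipping them: a Gompertz–Makeham all-cause hazard
(5×10⁻⁴ + 3×10⁻⁵ e^{0.095·age}), and a lung-cancer hazard that is a
logistic-in-age fraction of it (midpoint 62 y, width 7 y, maximum 9.5%
males / 7.2% females) and zero below the sex-specific onset age (10 y
males, 20 y females — the ages below which lung-cancer deaths are
essentially unobserved). These defaults were fixed once so the analytic
baseline lifetime risk lands in the realistic 0.03–0.10 band (packaged
table: 0.077 males, 0.058 females) and are part of the packaged study
conditions. What the synthetic table does **not** emulate: cohort and
period effects, smoking-driven sex differences in hazard shape, infant
mortality, and the exact national age profile — so absolute risk curves
computed on it are illustrative, and tests passing on it demonstrate the
engine's correctness, not agreement with published national curves (which
require the real mortality tables, supported as CSV input).

`make_survey_table` draws regional surveys from lognormal concentration
distributions (the standard indoor-radon model; defaults GM 90/45/28 Bq/m³
and GSD 2.2/2.0/2.0 for home/school/public, in the range of the packaged
real compilation), reporting each survey by the arithmetic mean and SD of
its draws. All generators are pure functions of their config (seed
included).

`cohort_simulator` is the independent check on the life-table algebra: a
closed cohort walked year by year, dying with probability 1−exp(−H_i) and
attributing deaths to lung cancer with probability h_i(1+e_i)/H_i. Since
cohort members are exchangeable, the per-year counts are drawn as
Binomials on the aggregate, which leaves the estimator's distribution
identical to per-individual simulation while keeping 10⁶-member cohorts
effectively instant. Agreement with the analytic sum within 3 binomial
standard errors is asserted over a seeded grid of random hazard/ERR
scenarios.

## Numerical and design choices

* Year length 365 days; lifespan 110 years; ages are integer years.
* Full precision internally; half-away-from-zero rounding at display only.
* Daily hours must sum to 24 ± 0.01; mortality tables must satisfy
  0 ≤ h ≤ h* with h* > 0 at every age.
* Problem sizes in the test suite (10⁶-member cohorts, ~10-scenario
  Monte-Carlo grids) were chosen to make 3-SE agreement a sharp test while
  the whole suite stays in the seconds range.
* The packaged survey and time-activity fixtures are verbatim transcriptions
  of the source compilation (including the 24.2 Bq/m³ value discussed
  above).

## Known limitations

* No dosimetric lung-dose modelling, aerosol physics, or seasonal
  variation; F_eq values are configuration, not measurement.
* No smoking interaction or alternative risk models; no uncertainty
  propagation — point estimates only.
* Attribution shares are defined at the lifetime horizon (age 110);
  age-resolved attribution would need the same machinery per attained age.
* Detection-limit handling in surveys is "coded as missing"; no imputation.
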