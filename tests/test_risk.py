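import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radonrisk.exposure import LIFESPAN, LOCATIONS, ExposureHistory, build_lifetime_history
from radonrisk.risk import (
    MortalityTable,
    RiskParams,
    attribute_by_location,
    baseline_risk,
    err,
    err_series,
    lifetime_risk,
    load_mortality,
    relative_risk,
)

from conftest import toy_mortality


def uniform_history(wlm=1.0):
    arr = np.zeros((LIFESPAN, len(LOCATIONS)))
    arr[:, 0] = wlm
    return ExposureHistory(arr)


class TestRiskParams:
    def test_defaults(self, default_params):
        assert default_params.beta == 0.0634
        assert default_params.theta_15_24 == 0.78
        assert default_params.theta_25plus == 0.51
        assert default_params.lag == 5

    def test_phi_lookup(self, default_params):
        assert default_params.phi(54.9) == 1.0
        assert default_params.phi(55) == 0.57
        assert default_params.phi(65) == 0.29
        assert default_params.phi(75) == 0.09
        assert default_params.phi(110) == 0.09

    def test_phi_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            RiskParams(phi_breaks=(55,), phi_values=(0.5, 0.9))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            RiskParams(beta=0)
        with pytest.raises(ValueError):
            RiskParams(theta_15_24=1.5)
        with pytest.raises(ValueError):
            RiskParams(phi_breaks=(65, 55), phi_values=(1, 0.5, 0.2))


class TestERR:
    def test_hand_arithmetic(self, flat_phi_params):
        # windows (10, 10, 6) WLM at a=30 under a uniform 1 WLM/y history
        e = err(30, uniform_history(), flat_phi_params)
        assert e == pytest.approx(0.0634 * (10 + 0.78 * 10 + 0.51 * 6), rel=1e-12)

    def test_zero_history_gives_zero_everywhere(self, default_params):
        series = err_series(ExposureHistory(np.zeros((LIFESPAN, 4))), default_params)
        assert np.all(series == 0)

    def test_age_modifier_applies(self):
        params = RiskParams(phi_breaks=(55,), phi_values=(1.0, 0.5))
        assert err(60, uniform_history(), params) == pytest.approx(
            0.5 * err(60, uniform_history(), RiskParams(phi_breaks=(), phi_values=(1.0,)))
        )


class TestLifetimeRisk:
    def test_one_year_closed_form(self):
        mt = toy_mortality(0.02, 0.1)
        r = lifetime_risk(mt, np.zeros(LIFESPAN))
        expected = (0.02 / 0.1) * (1 - np.exp(-0.1))
        assert r.lifetime == pytest.approx(expected, abs=1e-10)

    def test_no_lung_cancer_hazard_means_no_risk(self):
        mt = MortalityTable("x", np.zeros(LIFESPAN), np.full(LIFESPAN, 0.01))
        r = lifetime_risk(mt, np.full(LIFESPAN, 2.0))
        assert r.lifetime == 0.0

    def test_cumulative_risk_is_monotone_and_bounded(self, mortality_by_sex):
        r = lifetime_risk(mortality_by_sex["male"], np.full(LIFESPAN, 0.5))
        assert np.all(np.diff(r.cumulative) >= 0)
        assert 0 <= r.lifetime <= 1

    def test_strictly_increasing_in_beta(self, mortality_by_sex, patterns):
        hist = build_lifetime_history(patterns)
        risks = []
        for beta in (0.01, 0.05, 0.1):
            params = RiskParams(beta=beta)
            risks.append(
                lifetime_risk(mortality_by_sex["male"], err_series(hist, params)).lifetime
            )
        assert risks[0] < risks[1] < risks[2]

    def test_increasing_in_single_year_exposure(self, mortality_by_sex, flat_phi_params):
        base = uniform_history(0.5)
        bumped = base.wlm.copy()
        bumped[30, 0] += 5.0
        mt = mortality_by_sex["male"]
        r_base = lifetime_risk(mt, err_series(base, flat_phi_params)).lifetime
        r_bump = lifetime_risk(
            mt, err_series(ExposureHistory(bumped), flat_phi_params)
        ).lifetime
        assert r_bump > r_base

    def test_lag_exposure_after_105_never_matters(self, mortality_by_sex, default_params):
        base = uniform_history(1.0)
        late = base.wlm.copy()
        late[106:, 0] += 100.0
        mt = mortality_by_sex["female"]
        r_base = lifetime_risk(mt, err_series(base, default_params)).lifetime
        r_late = lifetime_risk(
            mt, err_series(ExposureHistory(late), default_params)
        ).lifetime
        assert r_late == pytest.approx(r_base, rel=1e-12)

    def test_hazard_conservation(self, mortality_by_sex):
        """Lung + other deaths each year equal total deaths; totals close
        to 1 - survival beyond the last age."""
        mt = mortality_by_sex["male"]
        e = np.full(LIFESPAN, 0.7)
        r = lifetime_risk(mt, e)
        total_hazard = mt.h_all + mt.h_lung * e
        total_deaths = r.survival * (1 - np.exp(-total_hazard))
        other_frac = (mt.h_all - mt.h_lung) / total_hazard
        other_deaths = other_frac * total_deaths
        np.testing.assert_allclose(r.yearly + other_deaths, total_deaths, rtol=1e-12)
        final_survival = r.survival[-1] * np.exp(-total_hazard[-1])
        assert total_deaths.sum() == pytest.approx(1 - final_survival, rel=1e-12)

    def test_printed_bracket_variant_is_lower(self, mortality_by_sex):
        mt = mortality_by_sex["male"]
        e = np.full(LIFESPAN, 1.0)
        corrected = lifetime_risk(mt, e, final_bracket="total_hazard").lifetime
        printed = lifetime_risk(mt, e, final_bracket="printed").lifetime
        assert printed < corrected

    def test_invalid_inputs(self, mortality_by_sex):
        with pytest.raises(ValueError):
            lifetime_risk(mortality_by_sex["male"], np.zeros(50))
        with pytest.raises(ValueError):
            lifetime_risk(mortality_by_sex["male"], np.full(LIFESPAN, -0.1))
        with pytest.raises(ValueError):
            MortalityTable("x", np.zeros(LIFESPAN), np.zeros(LIFESPAN))


class TestBaselineAndRelative:
    def test_baseline_equals_zero_err(self, mortality_by_sex):
        mt = mortality_by_sex["female"]
        assert baseline_risk(mt).lifetime == pytest.approx(
            lifetime_risk(mt, np.zeros(LIFESPAN)).lifetime
        )

    def test_baseline_zero_before_female_onset(self, mortality_by_sex):
        r0 = baseline_risk(mortality_by_sex["female"])
        assert r0.risk_at(19) == 0.0
        assert r0.risk_at(25) > 0.0

    def test_rr_is_one_without_exposure(self, mortality_by_sex):
        mt = mortality_by_sex["male"]
        base = baseline_risk(mt)
        rr = relative_risk(lifetime_risk(mt, np.zeros(LIFESPAN)), base)
        defined = ~np.isnan(rr)
        assert np.all(rr[defined] == pytest.approx(1.0))

    def test_rr_at_least_one_with_exposure(self, mortality_by_sex, patterns, default_params):
        mt = mortality_by_sex["female"]
        hist = build_lifetime_history(patterns)
        rr = relative_risk(lifetime_risk(mt, err_series(hist, default_params)), baseline_risk(mt))
        defined = ~np.isnan(rr)
        assert np.all(rr[defined] >= 1.0 - 1e-12)

    def test_rr_jumps_at_female_onset(self, mortality_by_sex, patterns, default_params):
        """Childhood exposure shows up as elevated RR as soon as the
        baseline becomes positive (around age 20 for females)."""
        mt = mortality_by_sex["female"]
        hist = build_lifetime_history(patterns)
        rr = relative_risk(lifetime_risk(mt, err_series(hist, default_params)), baseline_risk(mt))
        assert np.isnan(rr[18])  # age 19: no baseline yet
        assert rr[20] > 1.2  # age 21: accumulated childhood exposure


class TestAttribution:
    def test_single_location_gets_full_share(self, mortality_by_sex, patterns, default_params):
        home_only = {
            g: type(p)(
                p.age_group,
                p.hours,
                {loc: (v if loc == "home" else 0.0) for loc, v in p.eec_map.items()},
            )
            for g, p in patterns.items()
        }
        # zero EEC elsewhere: only home carries exposure
        shares = attribute_by_location(home_only, mortality_by_sex["male"], default_params)
        assert shares["home"] == pytest.approx(100.0)
        assert shares["outdoors"] == pytest.approx(0.0)

    def test_no_exposure_is_an_error(self, mortality_by_sex, patterns, default_params):
        none = {
            g: type(p)(p.age_group, p.hours, {loc: 0.0 for loc in p.eec_map})
            for g, p in patterns.items()
        }
        with pytest.raises(ValueError):
            attribute_by_location(none, mortality_by_sex["male"], default_params)

    def test_shares_sum_near_100_at_survey_exposures(
        self, mortality_by_sex, patterns, default_params
    ):
        shares = attribute_by_location(patterns, mortality_by_sex["male"], default_params)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1.0)

    def test_small_beta_limit_matches_windowed_exposure_shares(
        self, mortality_by_sex, patterns
    ):
        """As beta -> 0 the attribution converges to each location's share
        of the life-table-weighted windowed exposure (the linear limit)."""
        mt = mortality_by_sex["male"]
        shares_small = attribute_by_location(
            patterns, mt, RiskParams(beta=1e-6)
        )
        shares_tiny = attribute_by_location(
            patterns, mt, RiskParams(beta=1e-7)
        )
        for loc in shares_small:
            assert shares_small[loc] == pytest.approx(shares_tiny[loc], abs=1e-3)
        assert sum(shares_tiny.values()) == pytest.approx(100.0, abs=1e-3)


class TestMortalityIO:
    def test_roundtrip(self, tmp_path, mortality_by_sex):
        import pandas as pd

        frames = []
        for sex, t in mortality_by_sex.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "age": np.arange(1, LIFESPAN + 1),
                        "h_lung": t.h_lung,
                        "h_all": t.h_all,
                    }
                )
            )
        path = tmp_path / "mortality.csv"
        pd.concat(frames).to_csv(path, index=False)
        loaded = load_mortality(path)
        for sex, t in mortality_by_sex.items():
            np.testing.assert_allclose(loaded[sex].h_lung, t.h_lung)
            np.testing.assert_allclose(loaded[sex].h_all, t.h_all)

    def test_incomplete_table_rejected(self, tmp_path):
        import pandas as pd

        pd.DataFrame(
            {"sex": "male", "age": [1, 2], "h_lung": [0, 0], "h_all": [0.1, 0.1]}
        ).to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError):
            load_mortality(tmp_path / "m.csv")
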