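import numpy as np
import pytest

from radonrisk.exposure import LIFESPAN
from radonrisk.risk import MortalityTable, RiskParams
from radonrisk.survey import table1_surveys
from radonrisk.exposure import table2_patterns
from radonrisk.synthetic import SyntheticConfig, make_mortality_table


@pytest.fixture(scope="session")
def table1():
    return table1_surveys()


@pytest.fixture(scope="session")
def patterns():
    return table2_patterns()


@pytest.fixture(scope="session")
def default_params():
    return RiskParams()


@pytest.fixture(scope="session")
def flat_phi_params():
    """Risk params with no attained-age modification (phi == 1)."""
    return RiskParams(phi_breaks=(), phi_values=(1.0,))


@pytest.fixture(scope="session")
def synthetic_cfg():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def mortality_by_sex(synthetic_cfg):
    return {
        sex: make_mortality_table(synthetic_cfg, sex) for sex in ("male", "female")
    }


def toy_mortality(h_lung_first: float, h_all_first: float) -> MortalityTable:
    """One effective year of mortality: lung-cancer hazard only at age 1.

    Later ages carry a vanishing all-cause hazard and no lung cancer, so
    the lifetime risk equals the single-year closed form
    (h/h*) * (1 - exp(-h*)).
    """
    h = np.zeros(LIFESPAN)
    h[0] = h_lung_first
    h_star = np.full(LIFESPAN, 1e-12)
    h_star[0] = h_all_first
    return MortalityTable(sex="toy", h_lung=h, h_all=h_star)
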