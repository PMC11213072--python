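import numpy as np
import pytest

from mrdoc.synthetic_data import SyntheticScenario, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-design cohort under a moderate causal scenario, used by several
    fitting tests (session-scoped: simulation is cheap, fits are not)."""
    scenario = SyntheticScenario(
        g1=0.2, g2=0.1, b1=0.25, b3=0.25, r_a=0.3, iv_covariance=0.1, seed=11
    ).calibrated()
    return simulate_cohort(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
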