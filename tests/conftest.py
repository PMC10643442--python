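import numpy as np
import pandas as pd
import pytest

from dyadmr import ScenarioParams, simulate_couples


@pytest.fixture(scope="session")
def interaction_cohort():
    """Mid-sized interaction cohort reused across analysis tests."""
    params = ScenarioParams(
        scenario="interaction", n_couples=4000, alpha_g=0.3, beta_i=0.2,
        n_snps=15, seed=42,
    )
    return simulate_couples(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_regression_fixture(rng):
    """8-row deterministic regression fixture with one covariate."""
    x = np.array([1.0, 2.0, 3.0, 4.0, 2.5, 3.5, 1.5, 4.5])
    c = np.array([0.2, -0.1, 0.4, 0.0, 0.3, -0.2, 0.1, 0.5])
    y = 0.5 * x - 0.8 * c + np.array(
        [0.05, -0.02, 0.11, -0.07, 0.03, 0.09, -0.04, 0.01]
    )
    return x, y, c
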