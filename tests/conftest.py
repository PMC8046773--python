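import numpy as np
import pytest

from teloscore_mr.simulate import (SimConfig, default_panel_with_synthetic_weights,
                                   simulate_study)


@pytest.fixture(scope="session")
def weighted_panel():
    return default_panel_with_synthetic_weights()


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study (2407 cases / 1741 controls target)."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SimConfig(n_cases=400, n_controls=300), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
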