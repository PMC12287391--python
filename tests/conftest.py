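import numpy as np
import pytest

from acti2img import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic cohort (4+4 participants, 1 day) for fast tests."""
    cfg = SimulationConfig(
        n_condition=4, n_control=4, days_per_participant=1, seed=7
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
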