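import numpy as np
import pytest

from twinliab.synthetic_cohort import preset_params, simulate_cohort


@pytest.fixture(scope="session")
def aged_cohort():
    """One simulated older-adult cohort (1220 pairs), shared across tests."""
    return simulate_cohort(preset_params("aged", seed=20240101))


@pytest.fixture(scope="session")
def te_cohort():
    """One simulated young-adult cohort (2363 pairs)."""
    return simulate_cohort(preset_params("te", seed=20240102))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
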