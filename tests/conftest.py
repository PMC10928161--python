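import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete synthetic cohort shared across tests."""
    from fetopulm.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_control=8, n_fgr=8, rng_seed=42))


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size cohort at the study arm sizes (one generation per session)."""
    from fetopulm.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
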