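import numpy as np
import pytest

from wallcast.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A default-condition cohort small enough for per-test reuse."""
    return generate_cohort(CohortConfig(n_runners=300, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)
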