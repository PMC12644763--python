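import numpy as np
import pytest

from sepstrat import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Single-center cohort of 600 patients, default study conditions."""
    return generate_cohort(GeneratorConfig(n_per_center=600, seed=11))


@pytest.fixture(scope="session")
def midsize_cohort():
    """2,000-patient cohort used by prevalence and gradient checks."""
    return generate_cohort(GeneratorConfig(n_per_center=2000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
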