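import numpy as np
import pytest

from atherobma import GeneratorConfig, generate_cohort, preprocess_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size cohort (3 CNTL / 4 HF / 6 HHF, 40 proteins)."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return preprocess_cohort(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
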