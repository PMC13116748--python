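import numpy as np
import pytest

from tipiscore import GeneratorConfig, generate_cohort, generate_table1_fixture


@pytest.fixture(scope="session")
def table1_cohort():
    """Deterministic 75-record cohort reproducing the published margin-by-outcome counts."""
    return generate_table1_fixture()


@pytest.fixture(scope="session")
def small_synthetic_cohort():
    """A 300-record synthetic cohort for exercising the full pipeline."""
    return generate_cohort(GeneratorConfig(n=300, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
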