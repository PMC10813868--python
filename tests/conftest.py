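import numpy as np
import pytest

from connqc import GeneratorConfig, generate_cohort, generate_quality


@pytest.fixture(scope="session")
def table1_config():
    return GeneratorConfig.from_preset("maastricht_table1", n=5110, seed=11)


@pytest.fixture(scope="session")
def cohort(table1_config):
    return generate_cohort(table1_config)


@pytest.fixture(scope="session")
def quality_table(table1_config, cohort):
    return generate_quality(cohort, table1_config)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig.from_preset("maastricht_table1", n=60, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_quality(small_config, small_cohort):
    return generate_quality(small_cohort, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
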