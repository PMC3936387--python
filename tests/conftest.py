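import pytest

from cwmfd import (
    DesignConfig,
    GeneratorConfig,
    default_pool,
    generate_experiment,
    gower_dissimilarity,
    run_design,
)
from cwmfd.microcosm_analysis import process_microcosms


@pytest.fixture(scope="session")
def pool():
    return default_pool()


@pytest.fixture(scope="session")
def dissim(pool):
    return gower_dissimilarity(pool, "consumption_rate")


@pytest.fixture(scope="session")
def design(pool):
    return run_design(pool, DesignConfig(seed=1))


@pytest.fixture(scope="session")
def experiment(design, pool):
    records, truth = generate_experiment(design, pool, GeneratorConfig(seed=2))
    return records, truth


@pytest.fixture(scope="session")
def processed(experiment, pool):
    records, _ = experiment
    return process_microcosms(records, pool)
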