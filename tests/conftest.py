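import pytest

from cbfreg.simulate import (
    SimulationConfig,
    generate_expression_tables,
    generate_leakage_experiment,
    generate_promoter_set,
)


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def leakage(config):
    return generate_leakage_experiment(config)


@pytest.fixture(scope="session")
def expression(config):
    return generate_expression_tables(config)


@pytest.fixture(scope="session")
def promoter_sim(config):
    target = [f"G{i:05d}" for i in range(44)]
    return generate_promoter_set(config, target_genes=target, n_genes=300)
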