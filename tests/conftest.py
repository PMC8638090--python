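import pytest

from akicea.pipeline import ModelConfig, default_config, run_psa


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    """Base-case synthetic model configuration."""
    return default_config(seed=0)


@pytest.fixture(scope="session")
def psa_results(config):
    """A small shared PSA run (200 draws) for aggregate-level tests."""
    return run_psa(config, n_draws=200, seed=7)
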