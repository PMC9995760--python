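import pytest

from cnmod.simulate import SimConfig, generate_catalog


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def default_catalog(default_config):
    return generate_catalog(default_config)


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    # ct_gene_spread=0 keeps every baseline exactly at ct_base_mean so
    # fold changes survive floating point exactly
    return SimConfig(seed=7, ct_noise_sd=0.0, ct_gene_spread=0.0, key_effect_log2fc=2.0)
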