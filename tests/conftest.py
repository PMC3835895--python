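import pytest

from tagdge.simulate import SimulationConfig, generate_unigenes


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=100,
        length_range=(100, 400),
        catg_free_fraction=0.1,
        library_size=20_000,
        error_rate=0.0,
        n_contaminant_reads=0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_unigenes(small_config):
    return generate_unigenes(small_config)
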