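import numpy as np
import pytest

from tfselect import synthetic_data as sd


@pytest.fixture(scope="session")
def small_fixture_config():
    """Compact fixture: quick to generate, still exercises every region class."""
    return sd.FixtureConfig(
        seed=11,
        n_genes=12,
        codons_per_gene=120,
        n_tf_genes=5,
        flank_len=1500,
        n_crms=8,
        crm_len=700,
        sample_size=20,
    )


@pytest.fixture(scope="session")
def small_fixture(small_fixture_config):
    fixture = sd.generate_fixture(small_fixture_config)
    population = sd.generate_population(fixture, small_fixture_config)
    return fixture, population
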