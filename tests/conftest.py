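import pytest
from hypothesis import HealthCheck, settings

from memodel.genome import default_trna_map, standard_codon_table
from memodel.synthetic import mini_coli

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ct():
    return standard_codon_table()


@pytest.fixture(scope="session")
def trna_map():
    return default_trna_map()


@pytest.fixture(scope="session")
def fx():
    """The canonical mini-coli bundle; tests must mutate copies only."""
    return mini_coli(seed=1)
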