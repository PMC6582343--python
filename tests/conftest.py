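import pytest

from mitoforge import simulate
from mitoforge.io_formats import TaxonomyTable


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=11)


@pytest.fixture(scope="session")
def truth(sim_config):
    return simulate.make_genome(sim_config)


@pytest.fixture(scope="session")
def refs():
    return simulate.reference_table()


@pytest.fixture(scope="session")
def taxonomy():
    return TaxonomyTable(simulate.TAXONOMY_ROWS)


@pytest.fixture(scope="session")
def genome_hits(truth, refs, sim_config):
    """Hit tables generated for the planted genome itself."""
    hom, trna, rrna = simulate.make_hits(
        [truth.genome], truth, None, sim_config)
    return hom, trna, rrna
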