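import pytest

from dister import (
    GeneRecord,
    GenomeAnnotation,
    KnownTU,
    KnownTUTable,
    SimulationConfig,
    simulate_genome,
)


@pytest.fixture
def toy_annotation():
    """Four genes (+, +, -, +) on a 5 kb circle.

    Adjacent pairs in order: (g1,g2) same-strand, (g2,g3) convergent,
    (g3,g4) divergent, and the wrap-around (g4,g1) same-strand.
    """
    genes = (
        GeneRecord("g1", 101, 400, "+"),
        GeneRecord("g2", 501, 900, "+"),
        GeneRecord("g3", 1001, 1600, "-"),
        GeneRecord("g4", 1701, 2400, "+"),
    )
    return GenomeAnnotation("toy", 5000, genes, circular=True)


@pytest.fixture
def toy_tus():
    return KnownTUTable(
        (
            KnownTU("t_exp", ("g1", "g2"), "experimental"),
            KnownTU("t_comp", ("g4", "g1"), "computational"),
        )
    )


@pytest.fixture(scope="session")
def sim_medium():
    """A 2,000-gene synthetic genome at the default study conditions."""
    return simulate_genome(SimulationConfig(n_genes=2000, seed=101))


@pytest.fixture(scope="session")
def sim_medium_config():
    return SimulationConfig(n_genes=2000, seed=101)
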