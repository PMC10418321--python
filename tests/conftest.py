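import pytest

from equomgs.genomics import build_ani_matrix
from equomgs.synthetic import (
    GenomePopulationSpec,
    default_pathway_proteins,
    simulate_genome_population,
)


@pytest.fixture(scope="session")
def pathway_proteins():
    return default_pathway_proteins()


@pytest.fixture(scope="session")
def default_population(pathway_proteins):
    """A default two-phylogroup population, shared across test modules."""
    return simulate_genome_population(
        GenomePopulationSpec(seed=11), proteins=pathway_proteins
    )


@pytest.fixture(scope="session")
def population_ani_matrix(default_population):
    return build_ani_matrix(default_population.genomes)
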