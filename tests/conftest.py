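import numpy as np
import pytest

from isomirkit.datasets import load_table1_fixture, load_table2_fixture
from isomirkit.filtering import FilterConfig, GenomeIndex, run_cascade
from isomirkit.simulate import (SimulationConfig, make_contaminants, make_loci,
                                simulate_experiment)


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table2():
    return load_table2_fixture()


@pytest.fixture(scope="session")
def small_genome_loci():
    """A small genome with 6 planted hairpin loci (seed fixed)."""
    return make_loci(40_000, 6, seed=3)


@pytest.fixture(scope="session")
def contaminants():
    return make_contaminants(seed=9)


@pytest.fixture(scope="session")
def small_experiment(small_genome_loci, contaminants):
    """One full simulated experiment plus its cascade results.

    5 tissues x 3 replicates at modest depth; shared across tests to keep
    the suite fast.
    """
    genome, loci = small_genome_loci
    config = SimulationConfig(seed=7, depth=12_000, dispersion=0.05)
    sims = simulate_experiment(loci, config, contaminants)
    index = GenomeIndex(genome)
    fconfig = FilterConfig(contaminant_set=tuple(contaminants))
    cascades = {lib_id: run_cascade(sim.records, index, loci, fconfig,
                                    library_id=lib_id)
                for lib_id, sim in sims.items()}
    return dict(genome=genome, loci=loci, config=config, sims=sims,
                cascades=cascades, index=index, fconfig=fconfig)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
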