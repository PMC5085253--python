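import numpy as np
import pytest

from mthet.reference import GeneFeature, MitoGenome
from mthet.simulate import TrioScenario, generate_trio_pileups, toy_mito_genome


@pytest.fixture(scope="session")
def mini_genome():
    """Hand-built 13 bp circular genome: one heavy-strand gene ATG GCT TAA.

    Layout: positions 1-2 D-loop, 3-11 protein gene, 12-13 intergenic.
    """
    genome = MitoGenome("CCATGGCTTAACC", circular=True)
    features = [
        GeneFeature("mini-dloop", 1, 2, "heavy", "dloop"),
        GeneFeature("mini-gene", 3, 11, "heavy", "protein"),
    ]
    return genome, features


@pytest.fixture(scope="session")
def mini_genome_light():
    """The same gene on the light strand: revcomp(ATGGCTTAA) at positions 3-11."""
    genome = MitoGenome("CC" + "TTAAGCCAT" + "CC", circular=True)
    features = [GeneFeature("mini-gene-L", 3, 11, "light", "protein")]
    return genome, features


@pytest.fixture(scope="session")
def toy_panel():
    """A small default-conditions trio panel shared by read-only tests."""
    scenario = TrioScenario(n_families=12, seed=7)
    genome, features = toy_mito_genome(seed=7)
    pileups, truth = generate_trio_pileups(scenario, genome=genome)
    return scenario, genome, features, pileups, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
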