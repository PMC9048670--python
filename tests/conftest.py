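import pytest

from abrep.profiling import ProfileStore
from abrep.retrieval import build_index
from abrep.simulate import SimulationConfig, packaged_germlines, simulate_repertoires


@pytest.fixture(scope="session")
def germlines():
    return packaged_germlines()


@pytest.fixture(scope="session")
def sim():
    """Three small heavy-chain studies with a 2% substitution rate."""
    cfg = SimulationConfig(
        n_studies=3, sequences_per_study=300, mutation_rate=0.02, seed=11
    )
    return simulate_repertoires(cfg)


@pytest.fixture(scope="session")
def reps(sim):
    return sim[0]


@pytest.fixture(scope="session")
def truth(sim):
    return sim[1]


@pytest.fixture(scope="session")
def gene_store(reps):
    return ProfileStore.build(reps, "gene", min_observations=20)


@pytest.fixture(scope="session")
def kmer_index(reps):
    return build_index(reps, k=5)
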