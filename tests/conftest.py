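import pytest

from meripkit.simulate import SimulationConfig, simulate_dataset

#: Desk-scale dataset shared by read-only tests (session scope for speed).
SMALL_CONFIG = SimulationConfig(n_genes=30, depth_per_library=20_000, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """(genome, annotation, simulation) for a 30-gene, 20k-depth run."""
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_genome(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_annotation(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_sim(small_dataset):
    return small_dataset[2]
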