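import numpy as np
import pytest

from enhancerstate import Genome, GenomicInterval, IntervalSet, SimulationConfig, simulate_dataset


@pytest.fixture
def toy_genome() -> Genome:
    return Genome((("chr1", 100_000), ("chr2", 50_000)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170)


def random_interval_set(
    rng: np.random.Generator, genome: Genome, n: int, max_width: int = 2000
) -> IntervalSet:
    ivs = []
    names = genome.names
    lengths = genome.sizes
    for _ in range(n):
        chrom = names[rng.integers(len(names))]
        start = int(rng.integers(0, lengths[chrom] - max_width))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(ivs, genome=genome)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return simulate_dataset(SimulationConfig(seed=7, noise_sigma=0.0))
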