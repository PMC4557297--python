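import numpy as np
import pytest

from chromark.core import ChromSizes, GenomicInterval, TagLibrary
from chromark.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chrom_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 100_000})


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared across read-only tests."""
    config = SimulationConfig(
        seed=42, n_genes=120, n_chroms=2, chrom_length=1_500_000
    )
    return simulate_dataset(config)


def random_intervals(rng, n, genome_length=100_000, chroms=("chr1",), max_len=2_000):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, genome_length - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, genome_length)))
    return out


def coverage_mask(intervals, genome_length=100_000, chrom="chr1"):
    """Per-base boolean coverage oracle."""
    mask = np.zeros(genome_length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask
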