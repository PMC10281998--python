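import numpy as np
import pytest

from tebind.io import GenomicInterval, PeakRecord, TECopy
from tebind.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_data():
    """One default simulated dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_interval(rng, chroms=("chr1", "chr2"), span=10_000, max_len=500):
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    start = int(rng.integers(0, span - max_len))
    length = int(rng.integers(1, max_len))
    strand = ["+", "-", "."][int(rng.integers(0, 3))]
    return GenomicInterval(chrom, start, start + length, strand)


def random_peak(rng, i, chroms=("chr1", "chr2"), span=100_000, width=200):
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    start = int(rng.integers(0, span - width))
    summit = int(rng.integers(start, start + width))
    return PeakRecord(GenomicInterval(chrom, start, start + width), summit, f"p{i}")


def random_te_copy(rng, i, subfamilies=("A", "B", "C"), chroms=("chr1", "chr2"),
                   span=100_000, consensus=100):
    sub = subfamilies[int(rng.integers(0, len(subfamilies)))]
    chrom = chroms[int(rng.integers(0, len(chroms)))]
    length = int(rng.integers(consensus // 2, consensus * 2))
    start = int(rng.integers(0, span - length))
    return TECopy(
        GenomicInterval(chrom, start, start + length),
        sub, f"fam_{sub}", f"class_{sub}", f"{sub}.{i}", consensus,
    )
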