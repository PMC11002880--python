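import numpy as np
import pytest

from epidyn.core import GenomicInterval, PeakRecord
from epidyn.synthetic import SimulationConfig, simulate_study


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


def peak(chrom, start, end, total=100.0, mx=10.0, sample="s1", mark="H3K18la"):
    return PeakRecord(iv(chrom, start, end), total, mx, sample, mark)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_genes=80,
        n_chroms=1,
        chrom_length=80 * 32_000,
        seed=5,
        lib_size_range=(400_000, 500_000),
        frag_lib_size_range=(30_000, 40_000),
        marks=("H3K18la", "H3K27me3"),
        focal_mark="H3K18la",
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=2000, max_len=300):
    """Small random interval sets for oracle-equivalence tests."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append((chrom, start, start + length))
    return out
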