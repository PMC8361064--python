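import numpy as np
import pytest

from methylcna import genome, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_bins():
    """50 bins over two small chromosomes, with GC fractions."""
    base = genome.build_bin_registry({"chr1": 30_000_000, "chr2": 20_000_000})
    gc = np.linspace(0.3, 0.6, len(base))
    return [
        genome.GenomicBin(b.chrom, b.start, b.end, float(g))
        for b, g in zip(base, gc)
    ]


@pytest.fixture
def small_config():
    return simulate.SimulationConfig(
        seed=11,
        chrom_lengths={"chr1": 30_000_000, "chr2": 20_000_000},
    )


@pytest.fixture
def toy_baseline(small_bins):
    """Hand-built baseline: md 0.70 +/- 0.05, counts 1.0 +/- 0.1."""
    n = len(small_bins)
    return genome.ReferenceBaseline(
        n_subjects=20,
        bins=small_bins,
        md_mean=np.full(n, 0.70),
        md_sd=np.full(n, 0.05),
        count_mean=np.full(n, 1.0),
        count_sd=np.full(n, 0.1),
        evaluable=np.ones(n, dtype=bool),
    )
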