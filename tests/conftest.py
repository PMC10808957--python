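import numpy as np
import pytest

from chromshift import GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_gene():
    """A single +-strand gene on chr1 at [10000, 15000) with three exons."""
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand="+",
        start=10_000,
        end=15_000,
        exons=[(10_000, 11_000), (12_000, 13_000), (14_000, 15_000)],
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=50):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return out
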