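import numpy as np
import pytest

from notokit.intervals import GenomeLayout, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_chrom_layout():
    return GenomeLayout({"chrA": 20_000, "chrB": 12_000})


def random_intervals(rng, n, chroms=("chrA", "chrB"), chrom_len=20_000, max_len=10_000):
    """Seeded random intervals for oracle-equivalence checks."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, chrom_len - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def bitmap_cover(intervals, chrom, length):
    """Per-base boolean oracle of union coverage on one chromosome."""
    bits = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            bits[iv.start : min(iv.end, length)] = True
    return bits
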