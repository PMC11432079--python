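"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from exonproxy.genomic_model import GenomicInterval
from exonproxy.simulator import make_fixture, thra_locus


# ---------------------------------------------------------------------------
# Per-base bitmap oracle for interval algebra
# ---------------------------------------------------------------------------


def bitmap(intervals, size=12_000):
    """Boolean per-base occupancy vector (index i <-> base i+1)."""
    bits = np.zeros(size, dtype=bool)
    for iv in intervals:
        bits[iv.start - 1 : iv.end] = True
    return bits


def bitmap_to_intervals(bits, seqname="chr", strand="+"):
    """Back-convert an occupancy vector to a sorted disjoint interval list."""
    out = []
    padded = np.concatenate([[False], bits, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for s, e in zip(edges[::2], edges[1::2]):
        out.append(GenomicInterval(seqname, int(s) + 1, int(e), strand))
    return out


def random_intervals(rng, n_max=8, coord_max=10_000, seqname="chr", strand="+"):
    n = rng.integers(0, n_max + 1)
    out = []
    for _ in range(n):
        start = int(rng.integers(1, coord_max))
        length = int(rng.integers(1, 500))
        out.append(
            GenomicInterval(seqname, start, min(start + length - 1, coord_max), strand)
        )
    return out


@pytest.fixture
def thra_fixture():
    return thra_locus()


@pytest.fixture
def toy_fixture():
    return make_fixture(seed=1)
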