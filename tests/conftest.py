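from __future__ import annotations

import numpy as np
import pytest

from rwmapkit.intervals import GenomicInterval, IntervalSet

BITMAP_N = 1000  # oracle universe [0, 1000)


def bitmap(s: IntervalSet, n: int = BITMAP_N) -> np.ndarray:
    """Per-basepair membership oracle for interval-set semantics."""
    out = np.zeros(n, dtype=bool)
    for start, end in s.spans:
        out[start:min(end, n)] = True
    return out


def set_from_bitmap(bits: np.ndarray, chrom: str = "5") -> IntervalSet:
    """Inverse of :func:`bitmap`, built by scanning runs of True."""
    ivs = []
    start = None
    for i, b in enumerate(bits):
        if b and start is None:
            start = i
        elif not b and start is not None:
            ivs.append(GenomicInterval(chrom, start, i))
            start = None
    if start is not None:
        ivs.append(GenomicInterval(chrom, start, len(bits)))
    return IntervalSet(ivs)


def random_interval_set(rng: np.random.Generator, n: int = BITMAP_N,
                        max_intervals: int = 8, chrom: str = "5") -> IntervalSet:
    k = int(rng.integers(0, max_intervals + 1))
    ivs = []
    for _ in range(k):
        a, b = sorted(rng.integers(0, n + 1, size=2))
        if a < b:
            ivs.append(GenomicInterval(chrom, int(a), int(b)))
    return IntervalSet(ivs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
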