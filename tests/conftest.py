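"""Shared fixtures and independent dense-mask oracles.

The mask oracle represents interval sets as per-base boolean arrays over a
toy chromosome, so union/intersection/counting are plain numpy boolean
algebra — a code path fully independent of the package's sweep-line
interval algebra.
"""
from __future__ import annotations

import numpy as np
import pytest

from oxichrom import SimConfig, simulate_all
from oxichrom.intervals import GenomicInterval


# ---------------------------------------------------------------------------
# Dense-mask oracle helpers


def mask_of(intervals, size: int, chrom: str = "toy") -> np.ndarray:
    """Boolean per-base occupancy of the intervals on one chromosome."""
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def random_intervals(rng, n: int, size: int, max_len: int = 500, chrom: str = "toy"):
    starts = rng.integers(0, size - 1, n)
    lengths = rng.integers(1, max_len + 1, n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + l, size)))
        for s, l in zip(starts, lengths)
        if min(s + l, size) > s
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20190828)


# ---------------------------------------------------------------------------
# Simulated study (expensive pieces are session-scoped)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study, coverage tracks included."""
    return simulate_all(SimConfig(seed=0))


@pytest.fixture(scope="session")
def light_bundle():
    """Default synthetic study without coverage tracks (fast)."""
    return simulate_all(SimConfig(seed=0), coverage=False)
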