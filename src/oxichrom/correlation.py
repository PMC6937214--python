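"""Replicate agreement: per-position Pearson correlation of coverage tracks.

Positions with zero read count in either replicate are filtered out before
correlating (an aligned merge of two zero-filtered per-position files keeps
exactly the jointly nonzero positions). Paired positions are kept
run-length encoded — the correlation over runs weighted by run length is
identical to the correlation over expanded per-base vectors, so whole
genomes never need densifying. A uniform random subsample (default
100,000 positions, seeded) is provided for plotting-scale summaries.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack, piecewise
from .errors import DegenerateError, ValidationError

#: Default number of randomly selected genomic positions for the subsample.
DEFAULT_SUBSAMPLE = 100_000
DEFAULT_SEED = 20190828


@dataclass
class PairedPositions:
    """Jointly nonzero positions of two tracks, run-length encoded.

    ``x[i]``, ``y[i]`` are the two read counts on a run of ``lengths[i]``
    consecutive positions starting at ``starts[i]`` on ``chroms[i]``.
    """

    chroms: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return int(self.lengths.sum())


def pair_and_filter(
    track1: CoverageTrack, track2: CoverageTrack, union: bool = False
) -> PairedPositions:
    """Align two tracks by genomic position and drop zero-count positions.

    Default (intersection): keep positions nonzero in *both* tracks. With
    ``union=True`` positions nonzero in either track are kept, zeros
    imputed — a sensitivity-check mode.
    """
    if track1.genome.chrom_sizes != track2.genome.chrom_sizes:
        raise ValidationError("tracks have mismatched genomes")
    chroms, starts, lengths, xs, ys = [], [], [], [], []
    for chrom in sorted(set(track1.runs) | set(track2.runs)):
        s, e, m = piecewise([track1, track2], chrom)
        keep = (m[0] > 0) & (m[1] > 0) if not union else (m[0] > 0) | (m[1] > 0)
        chroms.append(np.full(keep.sum(), chrom, dtype=object))
        starts.append(s[keep])
        lengths.append(e[keep] - s[keep])
        xs.append(m[0, keep])
        ys.append(m[1, keep])
    cat = lambda parts, dtype=None: (
        np.concatenate(parts) if parts else np.array([], dtype=dtype)
    )
    return PairedPositions(
        cat(chroms, object), cat(starts, np.int64), cat(lengths, np.int64),
        cat(xs, np.float64), cat(ys, np.float64),
    )


def pearson(paired: PairedPositions) -> float:
    """Product-moment correlation over the paired positions.

    Run lengths act as frequency weights, which is exactly the per-base
    correlation. Raises on fewer than two positions or zero variance.
    """
    n = len(paired)
    if n < 2:
        raise DegenerateError(f"need >= 2 paired positions, got {n}")
    w = paired.lengths.astype(np.float64)
    mx = np.average(paired.x, weights=w)
    my = np.average(paired.y, weights=w)
    dx, dy = paired.x - mx, paired.y - my
    vx = np.average(dx * dx, weights=w)
    vy = np.average(dy * dy, weights=w)
    if vx == 0 or vy == 0:
        raise DegenerateError("zero variance in one replicate; correlation undefined")
    return float(np.average(dx * dy, weights=w) / np.sqrt(vx * vy))


def subsample(
    paired: PairedPositions, n: int = DEFAULT_SUBSAMPLE, seed: int = DEFAULT_SEED
) -> PairedPositions:
    """Uniform sample without replacement of min(n, len) positions.

    Deterministic given the seed. Sampled positions come back as unit-length
    runs, so :func:`pearson` applies unchanged.
    """
    if n < 1:
        raise ValidationError(f"subsample size must be >= 1, got {n}")
    total = len(paired)
    k = min(n, total)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=k, replace=False))
    cum = np.concatenate(([0], np.cumsum(paired.lengths)))
    run = np.searchsorted(cum, idx, side="right") - 1
    offset = idx - cum[run]
    return PairedPositions(
        chroms=paired.chroms[run],
        starts=paired.starts[run] + offset,
        lengths=np.ones(k, dtype=np.int64),
        x=paired.x[run],
        y=paired.y[run],
    )
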