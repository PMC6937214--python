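"""Sparse per-base coverage tracks (bedGraph-backed run-length encoding).

A :class:`CoverageTrack` stores, per chromosome, sorted non-overlapping
runs ``[start, end) -> value``. Positions not covered by a run have value
0. Runs are kept as numpy arrays so window extraction, replicate
averaging, and joint-nonzero pairing are vectorized; a whole chromosome is
only densified on explicit request (fine for the toy genomes used in
simulation, deliberate for real ones via windowed access).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .intervals import Genome

Runs = dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]  # starts, ends, values


@dataclass
class CoverageTrack:
    runs: Runs
    genome: Genome

    @classmethod
    def from_runs(
        cls, runs: dict[str, list[tuple[int, int, float]]], genome: Genome
    ) -> "CoverageTrack":
        """Build from per-chromosome (start, end, value) triples.

        Runs are sorted and checked for overlap; adjacent equal-valued runs
        are coalesced and zero runs dropped.
        """
        packed: Runs = {}
        for chrom, triples in runs.items():
            if chrom not in genome.chrom_sizes:
                raise ValidationError(f"chromosome {chrom!r} not in genome")
            triples = sorted(triples)
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping coverage runs on {chrom}")
            if len(ends) and ends[-1] > genome.chrom_sizes[chrom]:
                raise ValidationError(f"coverage run beyond end of {chrom}")
            packed[chrom] = _coalesce(starts, ends, values)
        return cls(packed, genome)

    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray], genome: Genome) -> "CoverageTrack":
        """Run-length encode dense per-chromosome arrays."""
        packed: Runs = {}
        for chrom, arr in arrays.items():
            if chrom not in genome.chrom_sizes:
                raise ValidationError(f"chromosome {chrom!r} not in genome")
            if len(arr) != genome.chrom_sizes[chrom]:
                raise ValidationError(
                    f"dense array length {len(arr)} != {chrom} size "
                    f"{genome.chrom_sizes[chrom]}"
                )
            arr = np.asarray(arr, dtype=np.float64)
            if np.any(arr < 0):
                raise ValidationError("negative coverage values")
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            values = arr[starts]
            keep = values != 0
            packed[chrom] = (starts[keep], ends[keep], values[keep])
        return cls(packed, genome)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense values over [start, end); positions outside the chromosome
        (or uncovered) are 0. ``start`` may be negative and ``end`` may
        exceed the chromosome size — callers use this for summit flanks."""
        if chrom not in self.genome.chrom_sizes:
            raise ValidationError(f"chromosome {chrom!r} not in genome")
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.runs:
            return out
        starts, ends, values = self.runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(int(s), start) - start
            b = min(int(e), end) - start
            out[a:b] = v
        return out

    def dense(self, chrom: str) -> np.ndarray:
        """Whole-chromosome dense array (intended for small genomes)."""
        return self.values(chrom, 0, self.genome.chrom_sizes[chrom])

    def total_signal(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.runs.values())
        )


def _coalesce(starts, ends, values):
    keep = values != 0
    starts, ends, values = starts[keep], ends[keep], values[keep]
    if len(starts) == 0:
        return starts, ends, values
    out_s, out_e, out_v = [starts[0]], [ends[0]], [values[0]]
    for s, e, v in zip(starts[1:], ends[1:], values[1:]):
        if s == out_e[-1] and v == out_v[-1]:
            out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
            out_v.append(v)
    return (
        np.array(out_s, dtype=np.int64),
        np.array(out_e, dtype=np.int64),
        np.array(out_v, dtype=np.float64),
    )


def _check_same_genome(tracks: list[CoverageTrack]) -> Genome:
    genome = tracks[0].genome
    for t in tracks[1:]:
        if t.genome.chrom_sizes != genome.chrom_sizes:
            raise ValidationError("coverage tracks have mismatched genomes")
    return genome


def piecewise(tracks: list[CoverageTrack], chrom: str):
    """Common refinement of all tracks' runs on one chromosome.

    Yields ``(starts, ends, matrix)`` where ``matrix[i, j]`` is track i's
    value on segment j. Segments where every track is zero are dropped.
    """
    bounds = [np.array([0], dtype=np.int64)]
    for t in tracks:
        if chrom in t.runs:
            s, e, _ = t.runs[chrom]
            bounds.extend([s, e])
    cuts = np.unique(np.concatenate(bounds))
    size = tracks[0].genome.chrom_sizes[chrom]
    if len(cuts) == 0 or cuts[-1] != size:
        cuts = np.append(cuts, size)
    starts, ends = cuts[:-1], cuts[1:]
    matrix = np.zeros((len(tracks), len(starts)), dtype=np.float64)
    for i, t in enumerate(tracks):
        if chrom not in t.runs or len(t.runs[chrom][0]) == 0:
            continue
        ts, te, tv = t.runs[chrom]
        idx = np.searchsorted(ts, starts, side="right") - 1
        valid = (idx >= 0) & (starts < te[np.clip(idx, 0, None)])
        matrix[i, valid] = tv[idx[valid]]
    keep = matrix.any(axis=0)
    return starts[keep], ends[keep], matrix[:, keep]


def average_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-position arithmetic mean of replicate tracks.

    Positions absent from a track count as 0 for that track, matching the
    convention that bedGraph omissions mean zero coverage.
    """
    if not tracks:
        raise ValidationError("need at least one track to average")
    genome = _check_same_genome(tracks)
    runs: Runs = {}
    chroms = set().union(*(t.runs.keys() for t in tracks))
    for chrom in sorted(chroms):
        starts, ends, matrix = piecewise(tracks, chrom)
        runs[chrom] = _coalesce(starts, ends, matrix.mean(axis=0))
    return CoverageTrack(runs, genome)
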