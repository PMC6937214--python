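"""Readers and writers for BED3/BED6, ENCODE narrowPeak, ChromHMM
segmentation BED, and bedGraph.

Parsing is line-by-line so malformed records can be reported with their
line number. Lines starting with ``#``, ``track`` or ``browser`` are
skipped. Coordinates are taken as 0-based half-open exactly as written;
dialects are explicit, never sniffed. Writers emit tab-separated,
newline-terminated records.
"""
from __future__ import annotations

import os
from typing import IO, Iterable, Sequence

import numpy as np

from .coverage import CoverageTrack
from .errors import ParseError, ValidationError
from .intervals import Genome, GenomicInterval, Peak, Segmentation

DIALECTS = ("bed3", "bed6", "narrowPeak", "segmentation")

_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "segmentation": 4}


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Add or strip the ``chr`` prefix (``style`` = 'chr' or 'plain')."""
    bare = name[3:] if name.startswith("chr") else name
    return f"chr{bare}" if style == "chr" else bare


def _data_lines(handle: IO[str]):
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        yield lineno, line.split("\t") if "\t" in line else line.split()


def _interval(path, lineno, fields) -> GenomicInterval:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(path, lineno, f"bad BED coordinates: {exc}") from None
    if end <= start:
        raise ParseError(path, lineno, f"end {end} <= start {start}")
    try:
        return GenomicInterval(chrom, start, end)
    except ValidationError as exc:
        raise ParseError(path, lineno, str(exc)) from None


def read_bed(path: str | os.PathLike, dialect: str):
    """Read a BED-family file.

    Returns a list of :class:`GenomicInterval` (``bed3``), a list of
    :class:`Peak` (``bed6``/``narrowPeak``), or a :class:`Segmentation`
    (``segmentation``, label from the name column).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    min_cols = _MIN_COLS[dialect]
    out: list = []
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < min_cols:
                raise ParseError(
                    path, lineno,
                    f"{dialect} needs >= {min_cols} columns, got {len(fields)}",
                )
            iv = _interval(path, lineno, fields)
            if dialect == "bed3":
                out.append(iv)
            elif dialect == "segmentation":
                out.append((iv, fields[3]))
            else:
                name = fields[3] if fields[3] != "." else None
                try:
                    score = float(fields[4]) if fields[4] != "." else None
                except ValueError:
                    raise ParseError(path, lineno, f"bad score {fields[4]!r}") from None
                summit = pvalue = None
                if dialect == "narrowPeak":
                    try:
                        neglog_p = float(fields[7])
                        offset = int(fields[9])
                    except ValueError as exc:
                        raise ParseError(path, lineno, f"bad narrowPeak column: {exc}") from None
                    pvalue = float(10.0 ** -neglog_p) if neglog_p >= 0 else None
                    if offset >= 0:
                        summit = iv.start + offset
                try:
                    out.append(Peak(iv, summit=summit, score=score, pvalue=pvalue, name=name))
                except ValidationError as exc:
                    raise ParseError(path, lineno, str(exc)) from None
    if dialect == "segmentation":
        return Segmentation(out)
    return out


def write_bed(path: str | os.PathLike, items, header: Sequence[str] = ()) -> None:
    """Write intervals, peaks, or a Segmentation back out as BED/narrowPeak.

    Peaks with a summit are written as 10-column narrowPeak (p-value encoded
    as -log10 in column 8); bare intervals as BED3; (interval, label) pairs
    and Segmentations as 4-column segmentation BED.
    """
    records = items.records if isinstance(items, Segmentation) else items
    with open(path, "w") as handle:
        for line in header:
            handle.write(f"#{line}\n")
        for item in records:
            handle.write("\t".join(str(f) for f in _bed_fields(item)) + "\n")


def _bed_fields(item):
    if isinstance(item, GenomicInterval):
        return (item.chrom, item.start, item.end)
    if isinstance(item, tuple):  # (interval, label)
        iv, label = item
        return (iv.chrom, iv.start, iv.end, label)
    if isinstance(item, Peak):
        iv = item.interval
        neglog_p = -np.log10(item.pvalue) if item.pvalue is not None else -1
        offset = item.summit - iv.start if item.summit is not None else -1
        return (
            iv.chrom, iv.start, iv.end, item.name or ".",
            item.score if item.score is not None else 0, ".",
            0, f"{neglog_p:.6g}", -1, offset,
        )
    raise TypeError(f"cannot write {type(item).__name__} as BED")


def read_bedgraph(path: str | os.PathLike, genome: Genome) -> CoverageTrack:
    """Read a 4-column bedGraph into a run-length :class:`CoverageTrack`."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < 4:
                raise ParseError(path, lineno, f"bedGraph needs 4 columns, got {len(fields)}")
            iv = _interval(path, lineno, fields)
            try:
                value = float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, f"bad value {fields[3]!r}") from None
            if value < 0:
                raise ParseError(path, lineno, f"negative coverage {value}")
            if iv.chrom not in genome.chrom_sizes:
                raise ParseError(path, lineno, f"chromosome {iv.chrom!r} not in genome")
            if iv.end > genome.chrom_sizes[iv.chrom]:
                raise ParseError(
                    path, lineno,
                    f"interval end {iv.end} beyond {iv.chrom} size "
                    f"{genome.chrom_sizes[iv.chrom]}",
                )
            runs.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
    return CoverageTrack.from_runs(runs, genome)


def write_bedgraph(
    path: str | os.PathLike, track: CoverageTrack, header: Iterable[str] = ()
) -> None:
    """Write a coverage track as bedGraph; zero runs are omitted."""
    with open(path, "w") as handle:
        for line in header:
            handle.write(f"#{line}\n")
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
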