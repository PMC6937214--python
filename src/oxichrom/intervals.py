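"""Genomic interval data model and nucleotide-exact interval algebra.

All coordinates are 0-based half-open (BED convention). Intervals are
unstranded: none of the downstream analyses are strand-aware. The algebra
(:func:`merge`, :func:`intersect`, :func:`total_nt`) is the atom of every
nucleotide-counting step in the package — enrichment contingency tables,
peak-coverage fractions, gene-peak distances — so it is implemented here
once, with bookended intervals joining on merge so nucleotide counts are
never double-counted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit, score, p-value, name.

    The summit is an absolute genomic position (the base of maximum signal,
    narrowPeak column 10 offset added to the start). p-values live in (0, 1].
    """

    interval: GenomicInterval
    summit: int | None = None
    score: float | None = None
    pvalue: float | None = None
    name: str | None = None

    def __post_init__(self):
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValidationError(
                f"summit {self.summit} outside peak "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"p-value must be in (0, 1], got {self.pvalue}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def summit_or_midpoint(self) -> int:
        """Summit when called, else the peak midpoint (floor)."""
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class Genome:
    """Chromosome sizes plus the effective (mappable) genome size in bp.

    ``effective_size`` is the universe for nucleotide-level contingency
    tables; it defaults to the sum of chromosome sizes and may be smaller
    (e.g. the MACS2 hg19 convention of 2.7e9) but never larger.
    """

    chrom_sizes: dict[str, int]
    effective_size: int | None = None

    def __post_init__(self):
        if not self.chrom_sizes:
            raise ValidationError("genome must have at least one chromosome")
        for name, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive size")
        total = sum(self.chrom_sizes.values())
        if self.effective_size is None:
            object.__setattr__(self, "effective_size", total)
        elif not (0 < self.effective_size <= total):
            raise ValidationError(
                f"effective_size {self.effective_size} must be in (0, {total}]"
            )

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class Segmentation:
    """Labeled, non-overlapping intervals mapping the genome to state names.

    The canonical source is a ChromHMM dense-segmentation BED (label in the
    name column). Construction verifies that intervals sharing a chromosome
    are pairwise disjoint.
    """

    records: list[tuple[GenomicInterval, str]]
    labels: set[str] = field(init=False)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r[0].chrom, r[0].start))
        prev: GenomicInterval | None = None
        for iv, _label in self.records:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValidationError(
                    f"segmentation intervals overlap on {iv.chrom}: "
                    f"[{prev.start},{prev.end}) and [{iv.start},{iv.end})"
                )
            prev = iv
        self.labels = {label for _iv, label in self.records}

    def intervals_for(self, raw_labels: Iterable[str]) -> list[GenomicInterval]:
        """Merged union of all intervals carrying any of the given labels."""
        wanted = set(raw_labels)
        return merge([iv for iv, label in self.records if label in wanted])


# ---------------------------------------------------------------------------
# Interval algebra


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sorted, disjoint union of the input; bookended intervals are joined.

    Idempotent, and the result covers exactly the union of the input
    nucleotides, so downstream counts never double-count.
    """
    out: list[GenomicInterval] = []
    grouped = _by_chrom(intervals)
    for chrom in sorted(grouped):
        ivs = sorted(grouped[chrom], key=lambda iv: iv.start)
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def intersect(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two merged interval sets (two-pointer sweep)."""
    a_by, b_by = _by_chrom(a), _by_chrom(b)
    out: list[GenomicInterval] = []
    for chrom in sorted(set(a_by) & set(b_by)):
        xs, ys = a_by[chrom], b_by[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end < ys[j].end:
                i += 1
            else:
                j += 1
    return out


def total_nt(intervals: Iterable[GenomicInterval]) -> int:
    """Total nucleotides covered; inputs are assumed merged (disjoint)."""
    return sum(len(iv) for iv in intervals)


def covered_fraction(
    target: GenomicInterval, cover: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``target`` nucleotides covered by the merged set ``cover``."""
    hit = total_nt(intersect([target], cover))
    return hit / len(target)


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """bp between nearest ends of two intervals; 0 if they intersect.

    Returns None for intervals on different chromosomes (never comparable).
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))
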