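"""Distance-based linking of differentially expressed genes to ATAC peaks.

A gene is linked to every overlapping-class ATAC peak within a distance
threshold on the same chromosome, where distance is the gap between the
gene span and the peak interval: 0 when they intersect, else the bp
between nearest ends. The threshold is inclusive and direction-agnostic
(up- or downstream). The shipped thresholds are 0.5 and 1 Mb. A TSS
anchor mode measures from the gene's start coordinate instead of the span.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, ValidationError
from .intervals import Genome, GenomicInterval, Peak, gap_distance

DEFAULT_DISTANCES = (500_000, 1_000_000)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    interval: GenomicInterval
    logfc: float
    fdr: float
    name: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"gene {self.gene_id}: FDR {self.fdr} outside [0, 1]")


@dataclass(frozen=True)
class GenePeakLink:
    gene_id: str
    peak: Peak
    distance: int
    threshold: int


def read_gene_table(path, genome: Genome | None = None) -> list[GeneRecord]:
    """Read a TSV of gene_id, chrom, start, end, logfc, fdr (BED coords).

    With a genome given, genes on chromosomes absent from it are skipped
    (unplaced contigs), with a warning to stderr.
    """
    import sys

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end", "logfc", "fdr"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"gene table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if genome is not None and row.chrom not in genome.chrom_sizes:
            print(
                f"warning: gene {row.gene_id} on {row.chrom} absent from genome; skipped",
                file=sys.stderr,
            )
            continue
        out.append(
            GeneRecord(
                str(row.gene_id),
                GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                float(row.logfc),
                float(row.fdr),
                name=str(getattr(row, "gene_name", "")) or None,
            )
        )
    return out


def link(
    genes: list[GeneRecord],
    peaks: list[Peak],
    threshold: int,
    anchor: str = "span",
) -> list[GenePeakLink]:
    """All (gene, peak) pairs with gap distance <= threshold (inclusive).

    ``peaks`` should already be the overlapping-class ATAC peaks. With
    ``anchor='tss'`` the gene is reduced to a 1-bp point at its start.
    Each pair appears at most once; output order follows the input.
    """
    if threshold <= 0:
        raise ConfigError(f"distance threshold must be positive, got {threshold}")
    if anchor not in ("span", "tss"):
        raise ConfigError(f"anchor must be 'span' or 'tss', got {anchor!r}")
    out = []
    for gene in genes:
        giv = gene.interval
        if anchor == "tss":
            giv = GenomicInterval(giv.chrom, giv.start, giv.start + 1)
        for peak in peaks:
            d = gap_distance(giv, peak.interval)
            if d is not None and d <= threshold:
                out.append(GenePeakLink(gene.gene_id, peak, d, threshold))
    return out
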