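"""Nucleotide-level enrichment of a peak set in chromatin states or LADs.

For a peak set P and a genomic category C (a grouped set of chromatin
states, or a LAD annotation), the 2x2 contingency table counts
nucleotides::

                 in C        not in C
    in P          a             b
    not in P      c             d

with a + b + c + d = G_eff, the effective (mappable) genome size. A
one-sided Fisher exact test (alternative ``greater``, the default since
the scientific claim is overrepresentation) gives the hypergeometric tail
probability P[X >= a] with all margins fixed; ``two_sided`` sums point
probabilities no larger than the observed table's.

Because bases inside a peak are counted individually, the test treats
nucleotides as independent observations; p-values are reported raw, one
per category, with no multiple-testing correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, ValidationError
from .intervals import (
    Genome,
    GenomicInterval,
    Segmentation,
    intersect,
    merge,
    total_nt,
)

# Chromatin-state grouping keyed to the ENCODE ChromHMM 15-state dense
# segmentation labels (wgEncodeBroadHmm*): promoter = states 1+2, poised
# promoter = 3, strong enhancer = 4+5, poised/weak enhancer = 6+7,
# insulator = 8, repressed = 12, heterochromatin = 13. Label strings vary
# between releases, so the grouping is plain data and fully overridable.
DEFAULT_GROUPING: dict[str, set[str]] = {
    "promoter": {"1_Active_Promoter", "2_Weak_Promoter"},
    "poised_promoter": {"3_Poised_Promoter"},
    "strong_enhancer": {"4_Strong_Enhancer", "5_Strong_Enhancer"},
    "poised_weak_enhancer": {"6_Weak_Enhancer", "7_Weak_Enhancer"},
    "insulator": {"8_Insulator"},
    "repressed": {"12_Repressed"},
    "heterochromatin": {"13_Heterochrom/lo"},
}

#: MACS2-convention effective genome size for hg19 (bp).
HG19_EFFECTIVE_SIZE = 2_700_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """Nucleotide counts: peaks∩category, peaks only, category only, rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative contingency cell in {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    table: ContingencyTable
    odds_ratio: float
    fold_enrichment: float
    p_value: float
    alternative: str
    degenerate: bool = False


def group_states(
    seg: Segmentation, grouping: dict[str, set[str]]
) -> dict[str, list[GenomicInterval]]:
    """Merged intervals per output category (union over its raw labels).

    Raw labels absent from the segmentation's vocabulary raise
    :class:`ConfigError`; a category whose labels are present but carry no
    intervals yields an empty list.
    """
    unknown = set().union(*grouping.values()) - seg.labels
    if unknown:
        raise ConfigError(
            f"grouping refers to labels absent from the segmentation: "
            f"{sorted(unknown)}; available: {sorted(seg.labels)}"
        )
    return {name: seg.intervals_for(labels) for name, labels in grouping.items()}


def build_contingency(
    peaks: list[GenomicInterval],
    category: list[GenomicInterval],
    genome: Genome,
) -> ContingencyTable:
    """Nucleotide 2x2 table for merged peak and category interval sets.

    ``d`` is computed as the difference from the effective genome size.
    """
    a = total_nt(intersect(peaks, category))
    b = total_nt(peaks) - a
    c = total_nt(category) - a
    d = genome.effective_size - a - b - c
    if d < 0:
        raise ValidationError(
            f"peaks ∪ category cover {a + b + c} bp, exceeding the effective "
            f"genome size {genome.effective_size}; raise effective_size"
        )
    return ContingencyTable(a, b, c, d)


def fisher_enrichment(
    table: ContingencyTable, alternative: str = "greater", category: str = ""
) -> EnrichmentResult:
    """Fisher exact test of the table plus odds ratio and fold enrichment.

    Any zero margin makes the test degenerate (only one table is possible
    given the margins): p = 1.0 and ``degenerate`` is flagged.
    """
    if alternative not in ("greater", "two_sided"):
        raise ConfigError(f"alternative must be 'greater' or 'two_sided', got {alternative!r}")
    a, b, c, d = table.a, table.b, table.c, table.d
    n_peaks, n_cat, total = a + b, a + c, table.total

    if a * d > 0 and b * c == 0:
        odds = float("inf")
    elif b * c == 0:
        odds = 0.0 if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    fold = (
        (a / n_peaks) / (n_cat / total)
        if n_peaks > 0 and n_cat > 0
        else float("nan")
    )

    degenerate = 0 in (n_peaks, n_cat, b + d, c + d)
    if degenerate:
        p = 1.0
    elif alternative == "greater":
        # upper hypergeometric tail P[X >= a] with margins fixed
        p = float(stats.hypergeom.sf(a - 1, total, n_cat, n_peaks))
    else:
        p = float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])
    return EnrichmentResult(
        category=category,
        table=table,
        odds_ratio=odds,
        fold_enrichment=fold,
        p_value=min(p, 1.0),
        alternative=alternative,
        degenerate=degenerate,
    )


def enrich_all(
    peaks,
    seg: Segmentation,
    grouping: dict[str, set[str]] = None,
    genome: Genome = None,
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """One enrichment result per category of the grouping.

    ``peaks`` may be Peak objects or bare intervals; they are merged before
    counting so overlapping records never double-count nucleotides. Usable
    with a single-category grouping for LAD enrichment.
    """
    if genome is None:
        raise ConfigError("enrich_all requires a Genome (effective size)")
    if grouping is None:
        grouping = DEFAULT_GROUPING
    merged_peaks = merge(
        [p.interval if hasattr(p, "interval") else p for p in peaks]
    )
    out = []
    for name, category in group_states(seg, grouping).items():
        table = build_contingency(merged_peaks, category, genome)
        out.append(fisher_enrichment(table, alternative, category=name))
    return out
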