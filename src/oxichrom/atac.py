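"""ATAC-peak classification by H3K4ox overlap, and summit-aligned signal.

Significant ATAC peaks (p < 1e-5, strict, matching the peak caller's
unadjusted p-value) are split into *overlapping* peaks — more than 95% of
the peak's sequence covered by the union of H3K4ox peaks — and *orphan*
peaks (everything else). Both thresholds are strict inequalities.

For signal aggregation, peak windows are aligned by their summits (or
midpoints when no summit was called) into a matrix of replicate-averaged
read counts at 1-bp offsets; the linear metaprofile is the column sum of
that matrix divided by the control column sum at offset 0, so the control
profile is exactly 1 at the summit and every value is relative to the
maximum control signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageTrack, average_tracks
from .errors import DegenerateError, ValidationError
from .intervals import Peak, covered_fraction, merge

OVERLAPPING = "overlapping"
ORPHAN = "orphan"

#: Default significance threshold for ATAC peaks (strict: p < alpha).
DEFAULT_ALPHA = 1e-5
#: Default minimum covered fraction for the overlapping class (strict >).
DEFAULT_MIN_FRAC = 0.95
#: Default summit flank, bp each side at 1-bp resolution.
DEFAULT_FLANK = 2000


@dataclass(frozen=True)
class PeakClass:
    peak: Peak
    label: str
    covered_fraction: float


@dataclass
class SignalMatrix:
    """Summit-aligned per-peak signal: rows follow input peak order, columns
    are offsets -flank..+flank. ``truncated`` flags rows whose window ran
    past a chromosome end (out-of-bounds offsets contribute 0)."""

    values: np.ndarray
    offsets: np.ndarray
    peaks: list[Peak]
    condition: str = ""
    truncated: np.ndarray = field(default=None)

    @property
    def flank(self) -> int:
        return (self.values.shape[1] - 1) // 2


@dataclass
class MetaProfile:
    offsets: np.ndarray
    values: np.ndarray
    condition: str = ""


def filter_significant(atac_peaks: list[Peak], alpha: float = DEFAULT_ALPHA) -> list[Peak]:
    """Retain exactly the peaks with p-value strictly below ``alpha``."""
    for i, p in enumerate(atac_peaks):
        if p.pvalue is None:
            raise ValidationError(f"peak #{i} ({p.chrom}:{p.interval.start}) has no p-value")
    return [p for p in atac_peaks if p.pvalue < alpha]


def classify(
    atac_peaks: list[Peak],
    h3k4ox_peaks: list[Peak],
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[PeakClass]:
    """Partition ATAC peaks into overlapping/orphan by H3K4ox coverage.

    The H3K4ox set is merged internally so the covered fraction is against
    the union of H3K4ox nucleotides. ``overlapping`` iff the fraction is
    strictly greater than ``min_frac``.
    """
    chip = merge([p.interval if hasattr(p, "interval") else p for p in h3k4ox_peaks])
    out = []
    for p in atac_peaks:
        frac = covered_fraction(p.interval, chip)
        label = OVERLAPPING if frac > min_frac else ORPHAN
        out.append(PeakClass(p, label, frac))
    return out


def average_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-position mean over replicate coverage tracks."""
    return average_tracks(tracks)


def summit_matrix(
    peaks: list[Peak] | list[PeakClass],
    track: CoverageTrack,
    flank: int = DEFAULT_FLANK,
    condition: str = "",
) -> SignalMatrix:
    """Track values at summit + offset for offsets -flank..+flank, per peak."""
    peaks = [pc.peak if isinstance(pc, PeakClass) else pc for pc in peaks]
    offsets = np.arange(-flank, flank + 1)
    values = np.zeros((len(peaks), 2 * flank + 1), dtype=np.float64)
    truncated = np.zeros(len(peaks), dtype=bool)
    for i, p in enumerate(peaks):
        summit = p.summit_or_midpoint()
        values[i] = track.values(p.chrom, summit - flank, summit + flank + 1)
        size = track.genome.chrom_sizes[p.chrom]
        truncated[i] = summit - flank < 0 or summit + flank + 1 > size
    return SignalMatrix(values, offsets, peaks, condition, truncated)


def linear_profile(
    kd_matrix: SignalMatrix, ctrl_matrix: SignalMatrix
) -> tuple[MetaProfile, MetaProfile]:
    """Position-wise column sums normalized to the control summit sum.

    Returns (control profile, knockdown profile); the control profile is
    exactly 1.0 at offset 0.
    """
    if kd_matrix.values.shape != ctrl_matrix.values.shape:
        raise ValidationError("KD and control matrices must share peaks and offsets")
    if not np.array_equal(kd_matrix.offsets, ctrl_matrix.offsets):
        raise ValidationError("KD and control matrices must share offsets")
    ctrl_sum = ctrl_matrix.values.sum(axis=0)
    kd_sum = kd_matrix.values.sum(axis=0)
    denom = ctrl_sum[ctrl_matrix.flank]
    if denom <= 0:
        raise DegenerateError("control summit column sum is zero; cannot normalize")
    return (
        MetaProfile(ctrl_matrix.offsets, ctrl_sum / denom, ctrl_matrix.condition or "control"),
        MetaProfile(kd_matrix.offsets, kd_sum / denom, kd_matrix.condition or "kd"),
    )
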