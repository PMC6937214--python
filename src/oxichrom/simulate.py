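"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study's inputs on
a toy multi-chromosome genome, with *planted*, recoverable truth at every
stage: a chromatin-state segmentation with set genome fractions; ChIP
peaks with a set fraction of their nucleotides inside one target state;
ATAC peaks with known overlapping/orphan class labels and p-values
straddling the significance cutoff; summit-shaped coverage with a planted
knockdown/control accessibility fold change at overlapping-class peaks;
a TE count table with planted log2 fold changes; and genes placed at
exact gap distances from chosen overlapping peaks.

Every generator is a pure function of :class:`SimConfig`: each draws from
its own named RNG stream derived from the master seed, so identical
configs give byte-identical output files and adding a generator never
perturbs the others.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as oxio
from .atac import ORPHAN, OVERLAPPING
from .coverage import CoverageTrack
from .errors import ConfigError
from .intervals import (
    Genome,
    GenomicInterval,
    Peak,
    Segmentation,
    covered_fraction,
    gap_distance,
    merge,
)
from .tediff import KD, CONTROL, CountTable

_STREAMS = {"segmentation": 0, "peaks": 1, "coverage": 2, "te": 3, "genes": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def _default_states() -> dict[str, float]:
    # Fractions of the genome per raw ChromHMM-style label; the remainder is
    # unlabeled. Heterochromatin at 10% is the planted enrichment target.
    return {
        "1_Active_Promoter": 0.02,
        "2_Weak_Promoter": 0.02,
        "3_Poised_Promoter": 0.01,
        "4_Strong_Enhancer": 0.02,
        "5_Strong_Enhancer": 0.02,
        "6_Weak_Enhancer": 0.03,
        "7_Weak_Enhancer": 0.03,
        "8_Insulator": 0.02,
        "12_Repressed": 0.05,
        "13_Heterochrom/lo": 0.10,
    }


def _default_te_planted() -> dict[str, float]:
    return {"TE_up1": 1.0, "TE_up2": 1.0, "TE_down1": -1.0}


@dataclass
class SimConfig:
    """All knobs of the synthetic study, fully serializable.

    Defaults are the conditions the package is validated under: a
    3-chromosome toy genome (the first chromosome is long enough to host
    the farthest gene placement), 80% of ChIP-peak nucleotides planted in
    heterochromatin occupying 10% of the genome, 40 overlapping vs 60
    orphan ATAC peaks, a 1.8x knockdown accessibility gain at
    overlapping-class peaks, and TE families with ±1 planted log2FC.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 3_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    # Peak-free tail of chr1 where genes are placed at exact gaps from the
    # rightmost overlapping peak, so a planted gap IS the distance to the
    # nearest peak (nothing else lies outward of the anchor).
    gene_zone_chrom: str = "chr1"
    gene_zone_size: int = 1_600_000
    block_size: int = 5_000
    state_fractions: dict[str, float] = field(default_factory=_default_states)
    target_state: str = "13_Heterochrom/lo"

    n_chip_peaks: int = 200
    chip_peak_len: tuple[int, int] = (300, 800)
    target_fraction: float = 0.8

    n_overlapping: int = 40
    n_orphan: int = 60
    n_nonsig: int = 20
    atac_peak_len: tuple[int, int] = (200, 500)

    background_rate: float = 1.0
    summit_amplitude: float = 50.0
    summit_sigma: float = 150.0
    kd_fold_change: float = 1.8

    te_n_families: int = 30
    te_baseline_range: tuple[float, float] = (1e3, 1e6)
    te_dispersion: float = 0.005
    te_planted: dict[str, float] = field(default_factory=_default_te_planted)
    te_replicates: int = 2

    gene_gaps: tuple[int, ...] = (0, 400_000, 900_000, 1_500_000)
    genes_per_gap: int = 3
    gene_length: int = 2_000

    def genome(self) -> Genome:
        return Genome(dict(self.chrom_lengths))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        cfg = cls(**data)
        for key in ("chip_peak_len", "atac_peak_len", "gene_gaps"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg


# ---------------------------------------------------------------------------
# Segmentation


def simulate_segmentation(cfg: SimConfig) -> tuple[Segmentation, Genome]:
    """Tile the genome into fixed-size blocks and label them by state.

    The number of blocks per state is the rounded state fraction of the
    total block count, so realized per-state bp fractions sit within one
    block of the configured fractions. Block-to-state assignment is a
    seeded permutation; unassigned blocks stay unlabeled.
    """
    total_frac = sum(cfg.state_fractions.values())
    if total_frac > 1.0 + 1e-9:
        raise ConfigError(f"state fractions sum to {total_frac:.3f} > 1")
    if any(f < 0 for f in cfg.state_fractions.values()):
        raise ConfigError("state fractions must be non-negative")
    genome = cfg.genome()
    blocks = []  # (chrom, start)
    for chrom, size in cfg.chrom_lengths.items():
        for start in range(0, size - cfg.block_size + 1, cfg.block_size):
            blocks.append((chrom, start))
    n_blocks = len(blocks)
    counts = {s: round(f * n_blocks) for s, f in cfg.state_fractions.items()}
    if sum(counts.values()) > n_blocks:
        raise ConfigError("state fractions infeasible at this block size")
    rng = _rng(cfg.seed, "segmentation")
    order = rng.permutation(n_blocks)
    records = []
    pos = 0
    for state, k in counts.items():
        for idx in order[pos : pos + k]:
            chrom, start = blocks[idx]
            records.append(
                (GenomicInterval(chrom, start, start + cfg.block_size), state)
            )
        pos += k
    return Segmentation(records), genome


# ---------------------------------------------------------------------------
# Peaks


def _overlaps_any(chrom: str, start: int, end: int, placed: dict[str, list]) -> bool:
    return any(s < end and start < e for s, e in placed.get(chrom, ()))


def _place(rng, regions, length, placed, max_tries=200):
    """Uniform placement of an interval of ``length`` inside one of the
    candidate regions (weighted by placeable width), avoiding ``placed``."""
    widths = np.array([max(0, (e - s) - length + 1) for _c, s, e in regions], dtype=float)
    if widths.sum() == 0:
        raise ConfigError(f"no room to place an interval of length {length}")
    p = widths / widths.sum()
    for _ in range(max_tries):
        chrom, rs, re_ = regions[rng.choice(len(regions), p=p)]
        start = int(rng.integers(rs, re_ - length + 1))
        if not _overlaps_any(chrom, start, start + length, placed):
            placed.setdefault(chrom, []).append((start, start + length))
            return chrom, start
    raise ConfigError("could not place interval without overlap; genome too crowded")


def simulate_peaks(
    cfg: SimConfig, seg: Segmentation, genome: Genome
) -> tuple[list[Peak], list[Peak], dict[str, str]]:
    """ChIP peaks with planted state enrichment, plus classifiable ATAC peaks.

    Returns ``(chip_peaks, atac_peaks, truth)`` where ``truth`` maps ATAC
    peak names to their planted class: ``overlapping`` (placed >= 96%
    covered by ChIP peaks), ``orphan`` (< 90% covered), or ``nonsig``
    (p-value above the significance cutoff, any placement).
    """
    rng = _rng(cfg.seed, "peaks")
    zone_start = {
        c: (size - cfg.gene_zone_size if c == cfg.gene_zone_chrom else size)
        for c, size in cfg.chrom_lengths.items()
    }
    target = seg.intervals_for({cfg.target_state})
    target_regions = [
        (iv.chrom, iv.start, min(iv.end, zone_start[iv.chrom]))
        for iv in target
        if iv.start < zone_start[iv.chrom]
    ]
    genome_regions = [(c, 0, zone_start[c]) for c in cfg.chrom_lengths]

    lengths = rng.integers(cfg.chip_peak_len[0], cfg.chip_peak_len[1] + 1, cfg.n_chip_peaks)
    total_bp = int(lengths.sum())
    placed: dict[str, list] = {}
    chip: list[Peak] = []
    inside_bp = 0
    for i, length in enumerate(map(int, lengths)):
        go_inside = inside_bp < cfg.target_fraction * total_bp
        if go_inside:
            chrom, start = _place(rng, target_regions, length, placed)
            inside_bp += length
        else:
            # rejection-sample fully outside the target state so the
            # realized inside fraction stays at the planted value
            for _ in range(200):
                chrom, start = _place(rng, genome_regions, length, placed)
                iv = GenomicInterval(chrom, start, start + length)
                if covered_fraction(iv, target) == 0.0:
                    break
                placed[chrom].remove((start, start + length))
            else:
                raise ConfigError("could not place a peak outside the target state")
        iv = GenomicInterval(chrom, start, start + length)
        chip.append(
            Peak(iv, summit=start + length // 2,
                 score=float(rng.integers(100, 1000)),
                 pvalue=10.0 ** -float(rng.uniform(6, 10)),
                 name=f"ox_{i:03d}")
        )

    atac: list[Peak] = []
    truth: dict[str, str] = {}
    merged_chip = merge([p.interval for p in chip])
    atac_placed: dict[str, list] = {}
    big_chip = [p for p in chip if len(p.interval) >= cfg.atac_peak_len[1] + 20]

    def add_atac(iv, significant, label, idx):
        name = f"atac_{idx:03d}"
        length = len(iv)
        jitter = int(rng.integers(-length // 10, length // 10 + 1))
        summit = min(max(iv.start + length // 2 + jitter, iv.start), iv.end - 1)
        if significant:
            pvalue = 10.0 ** -float(rng.uniform(6, 9))
        else:
            pvalue = 10.0 ** -float(rng.uniform(1, 4.7))
        atac.append(Peak(iv, summit=summit, score=float(rng.integers(50, 500)),
                         pvalue=pvalue, name=name))
        truth[name] = label

    idx = 0
    for _ in range(cfg.n_overlapping):
        length = int(rng.integers(*_len_range(cfg.atac_peak_len)))
        for _ in range(200):
            host = big_chip[rng.integers(0, len(big_chip))].interval
            if rng.random() < 0.5:  # fully inside: covered fraction 1.0
                start = int(rng.integers(host.start, host.end - length + 1))
            else:
                # stick out by < 4% of the ATAC peak at the host edge
                over = int(rng.integers(1, max(2, length // 30)))
                start = host.start - over if rng.random() < 0.5 else host.end + over - length
            start = max(start, 0)
            iv = GenomicInterval(host.chrom, start, start + length)
            if iv.end > cfg.chrom_lengths[host.chrom]:
                continue
            if _overlaps_any(iv.chrom, iv.start, iv.end, atac_placed):
                continue
            if covered_fraction(iv, merged_chip) >= 0.96:
                atac_placed.setdefault(iv.chrom, []).append((iv.start, iv.end))
                add_atac(iv, True, OVERLAPPING, idx)
                idx += 1
                break
        else:
            raise ConfigError("could not place an overlapping ATAC peak")

    for j in range(cfg.n_orphan):
        length = int(rng.integers(*_len_range(cfg.atac_peak_len)))
        for _ in range(200):
            if j % 10 == 0:  # a few partially covered orphans near a ChIP edge
                host = big_chip[rng.integers(0, len(big_chip))].interval
                start = host.end - length // 2
                if start < 0 or start + length > cfg.chrom_lengths[host.chrom]:
                    continue
                iv = GenomicInterval(host.chrom, start, start + length)
            else:
                combined = {c: placed.get(c, []) + atac_placed.get(c, []) for c in cfg.chrom_lengths}
                chrom, start = _place(rng, genome_regions, length, combined)
                iv = GenomicInterval(chrom, start, start + length)
            if _overlaps_any(iv.chrom, iv.start, iv.end, atac_placed):
                continue
            if covered_fraction(iv, merged_chip) < 0.90:
                atac_placed.setdefault(iv.chrom, []).append((iv.start, iv.end))
                add_atac(iv, True, ORPHAN, idx)
                idx += 1
                break
        else:
            raise ConfigError("could not place an orphan ATAC peak")

    for _ in range(cfg.n_nonsig):
        length = int(rng.integers(*_len_range(cfg.atac_peak_len)))
        combined = {c: atac_placed.get(c, []) for c in cfg.chrom_lengths}
        chrom, start = _place(rng, genome_regions, length, combined)
        atac_placed.setdefault(chrom, []).append((start, start + length))
        add_atac(GenomicInterval(chrom, start, start + length), False, "nonsig", idx)
        idx += 1

    return chip, atac, truth


def _len_range(rng_pair):
    return rng_pair[0], rng_pair[1] + 1


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    cfg: SimConfig,
    genome: Genome,
    atac_peaks: list[Peak],
    truth: dict[str, str],
) -> dict[str, CoverageTrack]:
    """Two control + two knockdown replicate tracks.

    Per-base counts are Poisson draws around a shared mean: a flat
    background plus a Gaussian-shaped bump at each significant ATAC peak's
    summit. At overlapping-class peaks the knockdown bump amplitude is
    ``kd_fold_change`` times the control amplitude; replicates are
    independent draws from the same mean.
    """
    rng = _rng(cfg.seed, "coverage")
    means = {
        cond: {c: np.full(size, cfg.background_rate) for c, size in genome.chrom_sizes.items()}
        for cond in ("ctrl", "kd")
    }
    half_width = int(4 * cfg.summit_sigma)
    for peak in atac_peaks:
        label = truth.get(peak.name, ORPHAN)
        if label == "nonsig":
            continue
        summit = peak.summit_or_midpoint()
        size = genome.chrom_sizes[peak.chrom]
        lo, hi = max(0, summit - half_width), min(size, summit + half_width + 1)
        x = np.arange(lo, hi)
        bump = np.exp(-0.5 * ((x - summit) / cfg.summit_sigma) ** 2)
        means["ctrl"][peak.chrom][lo:hi] += cfg.summit_amplitude * bump
        kd_amp = cfg.summit_amplitude * (
            cfg.kd_fold_change if label == OVERLAPPING else 1.0
        )
        means["kd"][peak.chrom][lo:hi] += kd_amp * bump

    tracks = {}
    for name, cond in (("ctrl1", "ctrl"), ("ctrl2", "ctrl"), ("kd1", "kd"), ("kd2", "kd")):
        arrays = {c: rng.poisson(mu).astype(np.float64) for c, mu in means[cond].items()}
        tracks[name] = CoverageTrack.from_dense(arrays, genome)
    return tracks


# ---------------------------------------------------------------------------
# TE count table


def simulate_te_table(cfg: SimConfig) -> tuple[CountTable, pd.Series]:
    """Negative-binomial TE family counts with planted log2 fold changes.

    Families named in ``te_planted`` carry the given log2FC (KD over
    control); the remaining families (padded to ``te_n_families``) are
    unchanged. Returns the count table and the truth series.
    """
    rng = _rng(cfg.seed, "te")
    planted = dict(cfg.te_planted)
    families = list(planted)
    families += [f"TE_{i:02d}" for i in range(cfg.te_n_families - len(families))]
    lfc = pd.Series({f: planted.get(f, 0.0) for f in families}, name="true_log2fc")

    lo, hi = cfg.te_baseline_range
    base = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), len(families))
    phi = cfg.te_dispersion
    samples = [f"ctrl{i+1}" for i in range(cfg.te_replicates)] + [
        f"kd{i+1}" for i in range(cfg.te_replicates)
    ]
    data = {}
    for s in samples:
        mu = base * (2.0 ** lfc.to_numpy() if s.startswith("kd") else 1.0)
        r = 1.0 / phi
        data[s] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(data, index=pd.Index(families, name="family"), dtype=float)
    conditions = {s: (KD if s.startswith("kd") else CONTROL) for s in samples}
    return CountTable(counts, conditions), lfc


# ---------------------------------------------------------------------------
# Genes


def simulate_genes(
    cfg: SimConfig, atac_peaks: list[Peak], truth: dict[str, str]
) -> pd.DataFrame:
    """Genes placed at exact gap distances from overlapping-class peaks.

    For each configured gap, ``genes_per_gap`` genes are placed up- or
    downstream of distinct overlapping peaks at exactly that gap (gap 0
    genes straddle their peak). Returns a gene table DataFrame with the
    anchor peak and true gap recorded for oracle checks.
    """
    rng = _rng(cfg.seed, "genes")
    hosts = [p for p in atac_peaks if truth.get(p.name) == OVERLAPPING]
    if not hosts:
        raise ConfigError("no overlapping peaks to anchor genes on")
    zone_chrom = cfg.gene_zone_chrom
    zone_hosts = sorted(
        (p for p in hosts if p.chrom == zone_chrom), key=lambda p: p.interval.end
    )
    if not zone_hosts:
        raise ConfigError(f"no overlapping peaks on {zone_chrom} to anchor far genes")
    anchor = zone_hosts[-1]  # rightmost peak: everything outward is peak-free
    size = cfg.chrom_lengths[zone_chrom]

    rows = []
    used: dict[str, list] = {}

    def add(gene_id, chrom, start, end, host, true_gap):
        used.setdefault(chrom, []).append((start, end))
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "logfc": float(rng.choice([-1, 1]) * rng.uniform(0.5, 3.0)),
                "fdr": 10.0 ** -float(rng.uniform(2, 10)),
                "gene_name": gene_id.upper(),
                "anchor_peak": host.name,
                "true_gap": true_gap,
            }
        )

    host_order = list(rng.permutation(len(hosts)))
    for gap in cfg.gene_gaps:
        for i in range(cfg.genes_per_gap):
            if gap == 0:
                for k in host_order:
                    host = hosts[k]
                    start = max(0, host.summit_or_midpoint() - cfg.gene_length // 2)
                    end = min(start + cfg.gene_length, cfg.chrom_lengths[host.chrom])
                    if end - start == cfg.gene_length and not _overlaps_any(
                        host.chrom, start, end, used
                    ):
                        add(f"gene_{gap}_{i}", host.chrom, start, end, host, 0)
                        break
                else:
                    raise ConfigError("could not place an overlapping gene")
            else:
                # siblings at the same nominal gap are staggered outward so
                # they never collide; each stays this side of the next
                # linking threshold
                true_gap = gap + i * 2 * cfg.gene_length
                start = anchor.interval.end + true_gap
                end = start + cfg.gene_length
                if end > size:
                    raise ConfigError(
                        f"gene at gap {true_gap} does not fit in the gene zone; "
                        f"enlarge {zone_chrom} or gene_zone_size"
                    )
                giv = GenomicInterval(zone_chrom, start, end)
                nearest = min(
                    gap_distance(giv, h.interval) for h in zone_hosts
                )
                assert nearest == true_gap, "gene zone contains a peak"
                add(f"gene_{gap}_{i}", zone_chrom, start, end, anchor, true_gap)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundle and fixture writing


@dataclass
class SimBundle:
    """Everything one simulated study produces, in memory."""

    config: SimConfig
    genome: Genome
    segmentation: Segmentation
    chip_peaks: list[Peak]
    atac_peaks: list[Peak]
    atac_truth: dict[str, str]
    tracks: dict[str, CoverageTrack]
    te_table: CountTable
    te_truth: pd.Series
    genes: pd.DataFrame


def simulate_all(cfg: SimConfig | None = None, coverage: bool = True) -> SimBundle:
    """Run every generator off one master seed."""
    cfg = cfg or SimConfig()
    seg, genome = simulate_segmentation(cfg)
    chip, atac, truth = simulate_peaks(cfg, seg, genome)
    tracks = simulate_coverage(cfg, genome, atac, truth) if coverage else {}
    te_table, te_truth = simulate_te_table(cfg)
    genes = simulate_genes(cfg, atac, truth)
    return SimBundle(cfg, genome, seg, chip, atac, truth, tracks, te_table, te_truth, genes)


def write_fixtures(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input as its on-disk format; returns the paths."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": outdir / "sim_config.yaml",
        "chrom_sizes": outdir / "chrom.sizes",
        "segmentation": outdir / "segmentation.bed",
        "h3k4ox": outdir / "h3k4ox.narrowPeak",
        "atac": outdir / "atac.narrowPeak",
        "te_counts": outdir / "te_counts.tsv",
        "te_truth": outdir / "te_truth.tsv",
        "genes": outdir / "genes.tsv",
        "atac_truth": outdir / "atac_truth.tsv",
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in bundle.genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    oxio.write_bed(paths["segmentation"], bundle.segmentation)
    oxio.write_bed(paths["h3k4ox"], bundle.chip_peaks)
    oxio.write_bed(paths["atac"], bundle.atac_peaks)
    for name, track in bundle.tracks.items():
        paths[name] = outdir / f"{name}.bedGraph"
        oxio.write_bedgraph(paths[name], track)
    bundle.te_table.counts.to_csv(paths["te_counts"], sep="\t")
    bundle.te_truth.rename_axis("family").to_csv(paths["te_truth"], sep="\t")
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False)
    pd.Series(bundle.atac_truth, name="label").rename_axis("peak").to_csv(
        paths["atac_truth"], sep="\t"
    )
    return paths
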