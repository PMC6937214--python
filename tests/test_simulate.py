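"""Synthetic-study generators: determinism, planted structure, re-parsing."""
import hashlib
from pathlib import Path

import numpy as np
import pytest

from oxichrom import (
    SimConfig,
    classify,
    filter_significant,
    intersect,
    merge,
    simulate_all,
    total_nt,
    write_fixtures,
)
from oxichrom import io as oxio
from oxichrom.atac import ORPHAN, OVERLAPPING
from oxichrom.errors import ConfigError
from oxichrom.simulate import (
    simulate_genes,
    simulate_peaks,
    simulate_segmentation,
    simulate_te_table,
)


def _small_config(**overrides) -> SimConfig:
    """A reduced study (sub-second coverage simulation) for heavy tests."""
    base = dict(
        chrom_lengths={"chr1": 1_000_000, "chr2": 300_000},
        gene_zone_size=500_000,
        gene_gaps=(0, 100_000, 460_000),
        genes_per_gap=2,
        n_chip_peaks=60,
        n_overlapping=10,
        n_orphan=15,
        n_nonsig=5,
    )
    base.update(overrides)
    return SimConfig(**base)


def _dir_digest(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestSegmentation:
    def test_single_state_covers_whole_genome(self):
        cfg = SimConfig(state_fractions={"X": 1.0})
        seg, genome = simulate_segmentation(cfg)
        assert total_nt(merge([iv for iv, _ in seg.records])) == genome.total_size

    def test_realized_fractions_within_two_percent(self):
        for seed in range(3):
            cfg = SimConfig(seed=seed)
            seg, genome = simulate_segmentation(cfg)
            for state, frac in cfg.state_fractions.items():
                got = total_nt(seg.intervals_for({state})) / genome.total_size
                assert got == pytest.approx(frac, abs=0.02)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ConfigError):
            simulate_segmentation(SimConfig(state_fractions={"A": 0.7, "B": 0.5}))

    def test_deterministic_per_seed(self):
        s1, _ = simulate_segmentation(SimConfig(seed=5))
        s2, _ = simulate_segmentation(SimConfig(seed=5))
        s3, _ = simulate_segmentation(SimConfig(seed=6))
        assert s1.records == s2.records
        assert s1.records != s3.records


class TestPeaks:
    def test_planted_target_fraction_within_three_percent(self, light_bundle):
        b = light_bundle
        target = b.segmentation.intervals_for({b.config.target_state})
        peak_ivs = merge([p.interval for p in b.chip_peaks])
        frac = total_nt(intersect(peak_ivs, target)) / total_nt(peak_ivs)
        assert frac == pytest.approx(b.config.target_fraction, abs=0.03)

    def test_planted_class_labels_recovered_exactly(self, light_bundle):
        b = light_bundle
        sig = filter_significant(b.atac_peaks)
        got = {c.peak.name: c.label for c in classify(sig, b.chip_peaks)}
        want = {k: v for k, v in b.atac_truth.items() if v != "nonsig"}
        assert got == want
        # and the nonsig peaks are exactly the filtered-out ones
        dropped = {p.name for p in b.atac_peaks} - set(got)
        assert dropped == {k for k, v in b.atac_truth.items() if v == "nonsig"}

    def test_zero_peaks_give_empty_outputs(self):
        cfg = SimConfig(n_chip_peaks=0, n_overlapping=0, n_orphan=0, n_nonsig=0,
                        genes_per_gap=0)
        seg, genome = simulate_segmentation(cfg)
        chip, atac, truth = simulate_peaks(cfg, seg, genome)
        assert chip == [] and atac == [] and truth == {}


class TestCoverage:
    def test_unit_fold_change_flat_ratio(self):
        cfg = _small_config(seed=2, kd_fold_change=1.0)
        b = simulate_all(cfg)
        ctrl = b.tracks["ctrl1"].total_signal() + b.tracks["ctrl2"].total_signal()
        kd = b.tracks["kd1"].total_signal() + b.tracks["kd2"].total_signal()
        assert kd / ctrl == pytest.approx(1.0, rel=0.02)

    def test_replicates_correlate_above_point_nine(self, default_bundle):
        from oxichrom import pair_and_filter, pearson

        b = default_bundle
        r = pearson(pair_and_filter(b.tracks["ctrl1"], b.tracks["ctrl2"]))
        assert r > 0.9


class TestTETable:
    def test_unchanged_families_estimate_near_zero(self):
        ests = []
        for seed in range(5):
            tab, truth = simulate_te_table(SimConfig(seed=seed, te_planted={}))
            from oxichrom import condition_means, tmm_factors

            means = condition_means(tab, tmm_factors(tab))
            ests.append(np.log2(means["kd_mean"] / means["ctrl_mean"]).to_numpy())
        assert abs(np.median(np.concatenate(ests))) < 0.05

    def test_planted_unit_log2fc_recovered(self):
        ests = []
        for seed in range(10):
            tab, truth = simulate_te_table(SimConfig(seed=seed))
            from oxichrom import condition_means, tmm_factors

            means = condition_means(tab, tmm_factors(tab))
            est = np.log2(means.loc["TE_up1", "kd_mean"] / means.loc["TE_up1", "ctrl_mean"])
            ests.append(est)
        assert np.median(ests) == pytest.approx(1.0, abs=0.1)

    def test_deterministic_per_seed(self):
        t1, _ = simulate_te_table(SimConfig(seed=8))
        t2, _ = simulate_te_table(SimConfig(seed=8))
        assert t1.counts.equals(t2.counts)


class TestGenes:
    def test_gap_400k_links_at_half_megabase(self, light_bundle):
        from oxichrom import GeneRecord, GenomicInterval, link

        b = light_bundle
        genes = [
            GeneRecord(r.gene_id, GenomicInterval(r.chrom, r.start, r.end),
                       r.logfc, r.fdr)
            for r in b.genes.itertuples(index=False)
        ]
        over = [p for p in b.atac_peaks if b.atac_truth[p.name] == OVERLAPPING]
        linked_half = {l.gene_id for l in link(genes, over, 500_000)}
        linked_one = {l.gene_id for l in link(genes, over, 1_000_000)}
        for r in b.genes.itertuples(index=False):
            assert (r.gene_id in linked_half) == (r.true_gap <= 500_000)
            assert (r.gene_id in linked_one) == (r.true_gap <= 1_000_000)

    def test_far_genes_never_link_at_shipped_thresholds(self, light_bundle):
        b = light_bundle
        far = b.genes[b.genes.true_gap >= 1_500_000]
        assert len(far) == b.config.genes_per_gap

    def test_placement_gap_is_nearest_peak_distance(self, light_bundle):
        from oxichrom.intervals import GenomicInterval, gap_distance

        b = light_bundle
        over = [p for p in b.atac_peaks if b.atac_truth[p.name] == OVERLAPPING]
        for r in b.genes.itertuples(index=False):
            giv = GenomicInterval(r.chrom, r.start, r.end)
            nearest = min(
                gap_distance(giv, p.interval) for p in over if p.chrom == r.chrom
            )
            assert nearest == r.true_gap


class TestFixtures:
    def test_byte_identical_per_seed_and_reparse(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        bundle = simulate_all(_small_config(seed=9))
        write_fixtures(bundle, d1)
        write_fixtures(simulate_all(_small_config(seed=9)), d2)
        assert _dir_digest(d1) == _dir_digest(d2)
        # every generated file re-parses without validation errors
        seg = oxio.read_bed(d1 / "segmentation.bed", "segmentation")
        chip = oxio.read_bed(d1 / "h3k4ox.narrowPeak", "narrowPeak")
        atac = oxio.read_bed(d1 / "atac.narrowPeak", "narrowPeak")
        assert seg.records and chip and atac
        for name in ("ctrl1", "ctrl2", "kd1", "kd2"):
            track = oxio.read_bedgraph(d1 / f"{name}.bedGraph", bundle.genome)
            for chrom in bundle.genome.chrom_sizes:
                assert np.allclose(
                    track.dense(chrom), bundle.tracks[name].dense(chrom)
                )
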