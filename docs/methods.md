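# Methods

`oxichrom` implements the downstream, nucleotide-level analyses of a
chromatin study contrasting a lysyl-oxidase knockdown (KD) with control
cells: where an oxidized-H3K4 (H3K4ox) ChIP-seq peak set sits among
chromatin states, how ATAC accessibility behaves at peaks that coincide
with H3K4ox, whether repetitive-element expression changes, and which
differential genes lie near the accessible peaks. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic study does and does not establish.

## Interval model

All coordinates are 0-based half-open (BED convention) and unstranded —
no analysis here is strand-aware. `merge` joins bookended intervals
(`[0,10) + [10,20) → [0,20)`): nucleotide counting is unaffected and the
algebra's invariants (idempotence, inclusion–exclusion) become exact.
Dialects (`bed3`, `bed6`, `narrowPeak`, ChromHMM `segmentation`,
`bedGraph`) are explicit, never sniffed, and chromosome-name mismatches
between files raise rather than silently dropping records
(`normalize_chrom` converts "chr1"/"1" styles on request).

## State enrichment (Fisher on nucleotides)

For peaks P and category C the 2×2 table counts *nucleotides*: a = |P∩C|,
b = |P|−a, c = |C|−a, d = G_eff−a−b−c, where G_eff is the effective
(mappable) genome size — for hg19 the peak-caller convention of
2.7×10⁹ bp, always overridable and required for synthetic genomes. Both
interval sets are merged first so overlapping records never double-count.
The default alternative is one-sided `greater` (the scientific claim is
overrepresentation); `two_sided` is a flag. The one-sided p-value is the
exact hypergeometric tail P[X ≥ a] with margins fixed; the two-sided
p-value sums point probabilities no larger than the observed table's.
p-values are reported raw, one per category, with no multiple-testing
correction (one figure-level test per state); the output header says so.

The shipped state grouping follows the 15-state ChromHMM convention:
promoter = states 1+2, poised promoter = 3, strong enhancer = 4+5,
poised/weak enhancer = 6+7, insulator = 8, repressed = 12,
heterochromatin = 13. Label strings vary between segmentation releases,
so the grouping is plain data and fully user-overridable; a
single-category grouping turns the same machinery into a LAD-enrichment
test.

Treating bases as independent observations is the method's defining
assumption. It is exact when single nucleotides are placed independently,
and anticonservative for multi-kb peaks (bases within a peak are
perfectly correlated). The null-calibration check therefore re-places
peak *nucleotides* (single-base intervals) uniformly — the granularity at
which the test's null holds — and observes ≈5% of category tests at
p < 0.05. A calibration under uniformly re-placed *whole peaks* would
measure the independence violation, not the implementation.

## ATAC–ChIP integration

Significant ATAC peaks are those with caller p-value strictly below 1e-5
(unadjusted; the upstream peak calling deliberately imposes no FDR cut so
the threshold can be chosen here). A significant peak is *overlapping*
when strictly more than 95% of its sequence is covered by the union of
H3K4ox peaks, else *orphan*; both thresholds are strict inequalities by
construction ("P < 1e-5", "more than 95%"), and the two classes partition
the input.

Replicate coverage tracks (bedGraph, run-length encoded; absent runs are
zero) are averaged per position, then windows of ±F bp (default
F = 2000, 1-bp bins; the display window is not dictated by the method, so
it is configurable) are extracted around each peak's summit — the
narrowPeak summit when called, otherwise the peak midpoint
(floor((start+end)/2)). Windows running past a chromosome end contribute
zeros and flag the row, keeping matrices rectangular. The linear
metaprofile is the per-offset column sum divided by the *control* column
sum at offset 0, so the control profile equals 1.0 at the summit exactly
and every value is relative to the maximum control signal. Averaging
replicates before or after window extraction is mathematically identical
for means; the stated order (average first) is implemented. Heatmap-style
row ordering (descending control row-sum) is display-only; matrices
preserve input order.

## Replicate correlation

Coverage positions with a zero count in either replicate are filtered
out; an aligned merge of two zero-filtered per-position files keeps
exactly the jointly nonzero positions, which is the default
(intersection) interpretation. A `union` mode (zeros imputed) exists for
sensitivity checks. Pairs stay run-length encoded; the Pearson
correlation weighted by run length is identical to the per-base
correlation, so whole genomes are never densified. The plotting-scale
subsample is 100,000 positions drawn uniformly without replacement
(default seed 20190828); both the full and subsampled r are reported
because the full-data value is the estimate and the subsample exists for
graphical representation.

## TE differential expression

The input is a family × sample table of aggregate repeat counts. Between-
sample normalization is TMM: against a reference sample (the one whose
75th-percentile relative abundance is closest to the across-sample mean —
the established convention), per-family log-ratios M and abundances A are
trimmed symmetrically (30% on M, 5% on A; families with a zero in either
sample excluded), and the scaling factor is 2^(weighted mean of surviving
M) with inverse asymptotic-variance weights. Factors are rescaled to
geometric mean exactly 1. The implementation is cross-checked in the test
suite against Bioconductor edgeR's `calcNormFactors` (agreement to 1e-9).

Condition means are counts scaled to a common normalized library size and
averaged within condition; log2FC is KD over control (the orientation the
published table uses: families with KD mean above control mean carry
positive log2FC). For comparison against printed 2-decimal values,
rounding is half-away-from-zero; raw values are always retained. Families
significant at the published rule are those with probability of
differential expression strictly above 0.95.

That probability comes from an external engine in the original analysis;
the package treats a supplied Prob column as first-class input. A
clearly-labelled permutation surrogate is available for self-contained
runs: the null pool collects per-family |log2FC| from condition-mixing
relabelings plus within-condition contrasts (the only noise contrasts a
2-vs-2 design affords), and the probability is the fraction of the pooled
null below the observed |log2FC|. Surrogate probabilities are a different
quantity from the external engine's and are never compared against the
published Prob column.

## Gene–peak linking

A differential gene links to every overlapping-class ATAC peak on the
same chromosome within an inclusive distance threshold (shipped
thresholds 0.5 and 1 Mb), where distance is the gap between the gene span
and the peak (0 on intersection, else bp between nearest ends),
direction-agnostic. Whether the original analysis anchored at the TSS or
the gene body is not stated; the span anchor is the default and a
`tss` anchor mode is provided. Links at 0.5 Mb are a subset of links at
1 Mb by construction.

## Synthetic study

The generator produces every input with planted, recoverable truth on a
toy genome; each generator draws from its own named RNG stream derived
from the master seed, so identical configs give byte-identical files and
generators never perturb each other. Defaults:

| parameter | default | why |
|---|---|---|
| genome | chr1 3 Mb, chr2/chr3 1 Mb | all stages run in seconds; chr1 hosts the gene zone |
| gene zone | last 1.6 Mb of chr1, peak-free | genes placed outward from the rightmost overlapping peak have their planted gap as the exact nearest-peak distance, so a 1.5 Mb gene can *never* link at the shipped thresholds |
| state fractions | heterochromatin 0.10, others 0.01–0.05, 5 kb blocks | planted enrichment target occupies 10% of the genome |
| ChIP peaks | 200 peaks, 300–800 bp, 80% of bp in heterochromatin | strong, unambiguous planted enrichment |
| ATAC peaks | 40 overlapping (placed ≥96% covered), 60 orphan (<90%), 20 non-significant | classes sit clear of the strict 95% boundary on both sides; p-values straddle 1e-5 |
| coverage | background 1.0, summit amplitude 50, σ = 150 bp, Poisson replicates | amplitude ≫ background so the summit-column KD/control ratio approaches the planted fold change (1.8×) |
| TE table | 30 families, baselines 10³–10⁶ (log-uniform), NB dispersion 0.005, planted log2FC ±1 | family-aggregate counts are sums over thousands of elements; a ~7% CV between replicates is realistic for such aggregates, and the planted effect is recoverable to <0.1 in the median over seeds |

What the synthetic study does *not* emulate: mappability structure, GC
bias, fragment-length effects, peak-shape heterogeneity, biological
replicate variability beyond counting noise, and the real genome's state
composition. Passing the planted-recovery tests therefore demonstrates
that the estimators and thresholds do what they claim on data satisfying
their assumptions — not that the published effect sizes are reproduced on
the deposited data, which the package never downloads. In particular the
published replicate correlation (r = 0.997) and the published heatmaps
are properties of the external accession and are out of scope; the
packaged TE reference table is the one in-paper dataset the package
regresses against.

Problem sizes used by the multi-seed recovery checks (a reduced
1.3 Mb study, 10–30 seeds) are the package's own choice of precision
versus runtime; the estimators are identical at every scale.

## Numerical choices and degenerate inputs

- Fisher: any zero margin makes the table the only one possible, so
  p = 1.0 with a `degenerate` flag; odds ratio is ad/bc with +∞ when
  bc = 0 and ad > 0.
- Metaprofile: a zero control summit column-sum is an error (nothing to
  normalize to), not a NaN.
- Correlation: fewer than two paired positions, or zero variance in
  either replicate, is an error rather than a silent NaN.
- TE: zero-count families are excluded from TMM trimming and carry ±∞
  log2FC with a flag, never silently dropped; permutation probabilities
  use a 0.5 pseudo-count.
- CLI exit codes: 0 success, 2 configuration error, 3 data validation
  error, 4 numeric degeneracy; every output file header records the tool
  version, subcommand, and full parameter set.

## Known limitations

- The nucleotide-level Fisher test inherits its anticonservatism on real
  multi-kb peaks from the method itself; the package reproduces the
  method, it does not repair it.
- The permutation surrogate for TE probabilities is coarse in a 2-vs-2
  design (few distinct relabelings); it is meant for synthetic data and
  sanity checks, not as a substitute for a dedicated engine.
- bigWig input is not supported (bedGraph only), and peak calling,
  alignment, and segmentation training are out of scope — the package
  consumes their outputs.
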