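"""Differential expression of transposable-element families.

A family x sample count table (aggregate read counts per TE family, e.g.
TEtools output) is normalized between samples with TMM — the trimmed mean
of M-values — and summarized per family as normalized condition means,
log2 fold change (knockdown over control), a probability of differential
expression, and a significance flag (probability strictly above 0.95).

TMM computes, for each sample against a reference sample, per-family
log-ratios M_g = log2((y_gs/N_s)/(y_gr/N_r)) and average abundances
A_g = 0.5*log2((y_gs/N_s)(y_gr/N_r)); after symmetric trimming (default
30% on M, 5% on A) the scaling factor is 2 to the variance-weighted mean
of the surviving M values, with weights the inverse asymptotic binomial
variances. Factors are rescaled to geometric mean 1.

The probability of differential expression is external input by design
(the study's engine is a separate package); a permutation surrogate is
offered for synthetic/self-contained runs, and its probabilities are a
different quantity from the externally supplied column — the two are never
mixed.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from math import copysign, floor, isfinite

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateError, ValidationError

CONTROL = "control"
KD = "kd"

#: Strict significance threshold on the probability of differential expression.
DEFAULT_PROB_THRESHOLD = 0.95
DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05


@dataclass
class CountTable:
    """Non-negative counts for TE families (rows) across samples (columns)."""

    counts: pd.DataFrame
    conditions: dict[str, str]  # sample -> "control" | "kd"

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate family names in count table")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts in count table")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValidationError(f"samples without a condition label: {sorted(missing)}")
        for cond in (CONTROL, KD):
            if not any(v == cond for v in self.conditions.values()):
                raise ValidationError(f"need at least one {cond!r} sample")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass(frozen=True)
class TEResult:
    family: str
    ctrl_mean: float
    kd_mean: float
    log2fc: float
    prob: float | None = None
    significant: bool = False
    flagged: bool = False  # infinite/undefined log2fc


def read_count_table(path, ctrl: list[str], kd: list[str]) -> CountTable:
    """Read a TSV count table (first column = family) with given sample split."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    conditions = {s: CONTROL for s in ctrl} | {s: KD for s in kd}
    unknown = set(conditions) - set(df.columns)
    if unknown:
        raise ConfigError(f"samples not in count table: {sorted(unknown)}")
    return CountTable(df[list(conditions)], conditions)


def load_te_reference_table() -> pd.DataFrame:
    """Packaged TE differential-expression reference table.

    Columns: family, ctrl_mean, kd_mean, prob, log2fc — normalized condition
    means, probability of differential expression, and the published
    2-decimal log2 fold change (KD over control) for 70 repeat families.
    """
    ref = importlib.resources.files("oxichrom.data") / "te_table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# TMM normalization


def _choose_reference(frac: np.ndarray) -> int:
    """edgeR-convention reference: sample whose 75th-percentile relative
    abundance is closest to the across-sample mean of those percentiles."""
    q75 = np.quantile(frac, 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def tmm_factors(
    table: CountTable,
    trim_m: float = DEFAULT_TRIM_M,
    trim_a: float = DEFAULT_TRIM_A,
    reference: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean exactly 1.

    Families with a zero count in either the sample or the reference are
    excluded before trimming (their M is infinite).
    """
    y = table.counts.to_numpy(dtype=np.float64)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, n in zip(table.counts.columns, lib) if n <= 0]
        raise ValidationError(f"samples with zero library size: {bad}")
    frac = y / lib
    samples = list(table.counts.columns)
    if reference is None:
        r = _choose_reference(frac)
    else:
        if reference not in samples:
            raise ConfigError(f"reference sample {reference!r} not in table")
        r = samples.index(reference)

    factors = np.ones(len(samples))
    for s in range(len(samples)):
        if s == r:
            continue
        factors[s] = _pair_factor(y[:, s], lib[s], y[:, r], lib[r], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _pair_factor(ys, ns, yr, nr, trim_m, trim_a) -> float:
    ok = (ys > 0) & (yr > 0)
    ys, yr = ys[ok], yr[ok]
    if len(ys) == 0:
        return 1.0
    m = np.log2((ys / ns) / (yr / nr))
    a = 0.5 * np.log2((ys / ns) * (yr / nr))
    w = (ns - ys) / (ns * ys) + (nr - yr) / (nr * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = floor(n * trim_m) + 1, n - floor(n * trim_m)
    lo_a, hi_a = floor(n * trim_a) + 1, n - floor(n * trim_a)
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    return float(2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def condition_means(table: CountTable, factors: pd.Series) -> pd.DataFrame:
    """Per-family normalized means for control and knockdown.

    Counts are scaled to a common library size: count / (N_s * f_s) times
    the mean effective library size, then averaged within each condition.
    """
    y = table.counts
    eff = y.sum(axis=0) * factors[y.columns]
    scaled = y / eff * eff.mean()
    return pd.DataFrame(
        {
            "ctrl_mean": scaled[table.samples(CONTROL)].mean(axis=1),
            "kd_mean": scaled[table.samples(KD)].mean(axis=1),
        }
    )


def log2fc(ctrl_mean: float, kd_mean: float) -> float:
    """log2(kd/ctrl); ±inf when exactly one mean is zero, NaN when both are."""
    if ctrl_mean < 0 or kd_mean < 0:
        raise ValidationError("negative condition mean")
    if ctrl_mean == 0 and kd_mean == 0:
        return float("nan")
    if ctrl_mean == 0:
        return float("inf")
    if kd_mean == 0:
        return float("-inf")
    return float(np.log2(kd_mean / ctrl_mean))


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the published table)."""
    if not isfinite(value):
        return value
    scale = 10 ** ndigits
    return copysign(floor(abs(value) * scale + 0.5) / scale, value)


def te_results(
    table: CountTable,
    factors: pd.Series | None = None,
    probs: pd.Series | None = None,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
) -> list[TEResult]:
    """Full per-family summary: normalized means, log2FC, significance."""
    if factors is None:
        factors = tmm_factors(table)
    means = condition_means(table, factors)
    out = []
    for family, row in means.iterrows():
        fc = log2fc(row["ctrl_mean"], row["kd_mean"])
        prob = None if probs is None else float(probs[family])
        out.append(
            TEResult(
                family=str(family),
                ctrl_mean=float(row["ctrl_mean"]),
                kd_mean=float(row["kd_mean"]),
                log2fc=fc,
                prob=prob,
                significant=prob is not None and prob > prob_threshold,
                flagged=not isfinite(fc),
            )
        )
    return out


def significance_filter(
    results: list[TEResult], prob_threshold: float = DEFAULT_PROB_THRESHOLD
) -> list[TEResult]:
    """Re-flag results: significant iff prob strictly above the threshold."""
    out = []
    for r in results:
        if r.prob is None:
            raise ValidationError(
                f"family {r.family!r} has no probability; supply one or use "
                "prob_from_permutation"
            )
        out.append(
            TEResult(
                r.family, r.ctrl_mean, r.kd_mean, r.log2fc,
                prob=r.prob, significant=r.prob > prob_threshold, flagged=r.flagged,
            )
        )
    return out


def prob_from_permutation(
    table: CountTable,
    factors: pd.Series | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation surrogate for the probability of differential expression.

    The null pool collects per-family |log2FC| values from relabelings of
    the samples that mix the two conditions, plus within-condition
    contrasts where a condition has >= 2 replicates (the only usable noise
    contrasts in a 2-vs-2 design). The probability for a family is the
    fraction of the pooled null below its observed |log2FC|. These are NOT
    the probabilities of the external engine used for the reference table —
    they are a self-contained surrogate for synthetic data.
    """
    if factors is None:
        factors = tmm_factors(table)
    y = table.counts
    eff = y.sum(axis=0) * factors[y.columns]
    scaled = (y / eff * eff.mean()).to_numpy() + 0.5  # pseudo-count stabilizes logs
    samples = list(y.columns)
    ctrl_idx = [samples.index(s) for s in table.samples(CONTROL)]
    kd_idx = [samples.index(s) for s in table.samples(KD)]

    def abs_m(ix, jx):
        return np.abs(np.log2(scaled[:, jx].mean(axis=1) / scaled[:, ix].mean(axis=1)))

    observed = abs_m(ctrl_idx, kd_idx)

    null_splits = []
    k = len(ctrl_idx)
    from itertools import combinations

    all_idx = ctrl_idx + kd_idx
    for left in combinations(all_idx, k):
        right = [i for i in all_idx if i not in left]
        if set(left) in (set(ctrl_idx), set(kd_idx)):
            continue  # the observed contrast (and its mirror) is not noise
        null_splits.append((list(left), right))
    for cond in (ctrl_idx, kd_idx):
        if len(cond) >= 2:
            half = len(cond) // 2
            null_splits.append((cond[:half], cond[half:]))
    if not null_splits:
        raise ValidationError("not enough replicates to build a permutation null")

    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(max(1, n_perm // len(null_splits))):
        for left, right in null_splits:
            # bootstrap families to grow the pool beyond the few exact splits
            fam = rng.integers(0, scaled.shape[0], size=scaled.shape[0])
            pool.append(abs_m(left, right)[fam])
    null = np.concatenate(pool)
    probs = np.searchsorted(np.sort(null), observed, side="left") / len(null)
    return pd.Series(probs, index=y.index, name="prob")
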