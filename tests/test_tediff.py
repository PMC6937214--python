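"""TMM normalization and TE differential-expression summaries."""
import shutil
import subprocess
from math import floor, log2

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from oxichrom import (
    CountTable,
    SimConfig,
    condition_means,
    load_te_reference_table,
    log2fc,
    prob_from_permutation,
    round_half_away,
    significance_filter,
    te_results,
    tmm_factors,
)
from oxichrom.errors import ValidationError
from oxichrom.simulate import simulate_te_table


def _table(data, n_ctrl=2):
    df = pd.DataFrame(data, dtype=float)
    df.index = [f"f{i}" for i in range(len(df))]
    samples = list(df.columns)
    conditions = {
        s: ("control" if i < n_ctrl else "kd") for i, s in enumerate(samples)
    }
    return CountTable(df, conditions)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        col = [100.0, 2000.0, 50.0, 800.0, 10.0, 400.0]
        tab = _table({"a": col, "b": col, "c": col, "d": col})
        assert np.allclose(tmm_factors(tab), 1.0)

    def test_depth_only_difference_gives_unit_factors(self):
        col = np.array([100.0, 2000.0, 50.0, 800.0, 10.0, 400.0])
        tab = _table({"a": col, "b": 2 * col, "c": col, "d": 5 * col})
        assert np.allclose(tmm_factors(tab), 1.0)

    def test_geometric_mean_exactly_one(self, rng):
        counts = rng.integers(1, 10_000, (40, 4)).astype(float)
        tab = _table({s: counts[:, i] for i, s in enumerate("abcd")})
        f = tmm_factors(tab)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_global_count_scaling(self, rng):
        counts = rng.integers(1, 10_000, (40, 4)).astype(float)
        t1 = _table({s: counts[:, i] for i, s in enumerate("abcd")})
        t2 = _table({s: 7.0 * counts[:, i] for i, s in enumerate("abcd")})
        assert np.allclose(tmm_factors(t1), tmm_factors(t2))

    def test_six_family_worked_example_matches_formula_oracle(self):
        """Literal step-by-step trimmed weighted mean, spelled out per family."""
        y = pd.DataFrame(
            {"s1": [1000.0, 200.0, 80.0, 6000.0, 30.0, 700.0],
             "s2": [2400.0, 190.0, 90.0, 5200.0, 25.0, 1400.0]},
            index=list("ABCDEF"),
        )
        tab = CountTable(y, {"s1": "control", "s2": "kd"})
        got = tmm_factors(tab, reference="s1")
        n1, n2 = y["s1"].sum(), y["s2"].sum()
        m, a_val, w = {}, {}, {}
        for fam in y.index:
            p2, p1 = y.loc[fam, "s2"] / n2, y.loc[fam, "s1"] / n1
            m[fam] = log2(p2 / p1)
            a_val[fam] = 0.5 * log2(p2 * p1)
            w[fam] = (n2 - y.loc[fam, "s2"]) / (n2 * y.loc[fam, "s2"]) + (
                n1 - y.loc[fam, "s1"]
            ) / (n1 * y.loc[fam, "s1"])
        fams = list(y.index)
        rm = rankdata([m[f] for f in fams])
        ra = rankdata([a_val[f] for f in fams])
        lo_m, hi_m = floor(6 * 0.30) + 1, 6 - floor(6 * 0.30)
        lo_a, hi_a = floor(6 * 0.05) + 1, 6 - floor(6 * 0.05)
        keep = [
            f for f, q, r in zip(fams, rm, ra)
            if lo_m <= q <= hi_m and lo_a <= r <= hi_a
        ]
        assert keep  # the trim leaves families behind
        f2 = 2 ** (
            sum(m[f] / w[f] for f in keep) / sum(1.0 / w[f] for f in keep)
        )
        expect = np.array([1.0, f2])
        expect /= np.exp(np.log(expect).mean())
        assert np.allclose(got.to_numpy(), expect, rtol=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_edger_reference_implementation(self, rng):
        """Independent cross-check against Bioconductor edgeR calcNormFactors."""
        counts = rng.integers(10, 5000, (25, 4)).astype(float)
        counts[0, 2:] *= 6
        tab = _table({s: counts[:, i] for i, s in enumerate("abcd")})
        mine = tmm_factors(tab).to_numpy()
        flat = ",".join(str(v) for v in counts.T.flatten())
        code = (
            "suppressMessages(library(edgeR));"
            f"m <- matrix(c({flat}), ncol=4);"
            'cat(sprintf("%.10f", calcNormFactors(m, method="TMM")), sep=",")'
        )
        out = subprocess.run(
            ["Rscript", "-e", code], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        theirs = np.array([float(v) for v in out.stdout.split(",")])
        assert np.allclose(mine, theirs, atol=1e-9)

    def test_zero_library_rejected(self):
        with pytest.raises(ValidationError, match="library"):
            tmm_factors(_table({"a": [1.0, 2.0], "b": [0.0, 0.0],
                                "c": [1.0, 1.0], "d": [1.0, 1.0]}))


class TestConditionMeans:
    def test_unit_factors_equal_libraries_reduce_to_raw(self):
        col = [10.0, 20.0, 30.0]
        tab = _table({"c1": col, "k1": col}, n_ctrl=1)
        means = condition_means(tab, pd.Series({"c1": 1.0, "k1": 1.0}))
        assert np.allclose(means["ctrl_mean"], col)
        assert np.allclose(means["kd_mean"], col)

    def test_duplicate_replicates_mean_is_the_replicate(self):
        col = [10.0, 20.0, 30.0]
        tab = _table({"c1": col, "c2": col, "k1": col, "k2": col})
        f = tmm_factors(tab)
        means = condition_means(tab, f)
        assert np.allclose(means["ctrl_mean"], means["kd_mean"])

    def test_matches_hand_rolled_oracle(self, rng):
        counts = rng.integers(1, 1000, (10, 4)).astype(float)
        tab = _table({s: counts[:, i] for i, s in enumerate(["c1", "c2", "k1", "k2"])})
        f = tmm_factors(tab)
        means = condition_means(tab, f)
        lib = counts.sum(axis=0)
        eff = lib * f.to_numpy()
        scaled = counts / eff * eff.mean()
        assert np.allclose(means["ctrl_mean"], scaled[:, :2].mean(axis=1))
        assert np.allclose(means["kd_mean"], scaled[:, 2:].mean(axis=1))


class TestLog2FC:
    @pytest.mark.parametrize(
        "family, expected",
        [("Alu", 0.04), ("RNA", 0.06), ("ERVK", 0.08),
         ("MIR", 0.04), ("hAT", 0.38), ("SVA_B", 0.17)],
    )
    def test_reference_table_means_reproduce_printed_log2fc(self, family, expected):
        ref = load_te_reference_table().set_index("family")
        fc = log2fc(ref.loc[family, "ctrl_mean"], ref.loc[family, "kd_mean"])
        assert round_half_away(fc, 2) == pytest.approx(expected)

    def test_whole_reference_table_consistent_at_2dp(self):
        ref = load_te_reference_table()
        for row in ref.itertuples(index=False):
            fc = round_half_away(log2fc(row.ctrl_mean, row.kd_mean), 2)
            assert fc == pytest.approx(row.log2fc, abs=0.011), row.family

    def test_equal_means_zero_and_edge_cases(self):
        assert log2fc(5.0, 5.0) == 0.0
        assert log2fc(0.0, 5.0) == float("inf")
        assert log2fc(5.0, 0.0) == float("-inf")
        assert np.isnan(log2fc(0.0, 0.0))

    def test_antisymmetry_under_condition_swap(self, rng):
        counts = rng.integers(1, 10_000, (20, 4)).astype(float)
        cols = ["c1", "c2", "k1", "k2"]
        t1 = _table({s: counts[:, i] for i, s in enumerate(cols)})
        swapped = CountTable(
            t1.counts, {"c1": "kd", "c2": "kd", "k1": "control", "k2": "control"}
        )
        f = tmm_factors(t1)
        m1 = condition_means(t1, f)
        m2 = condition_means(swapped, f)
        fc1 = np.log2(m1["kd_mean"] / m1["ctrl_mean"])
        fc2 = np.log2(m2["kd_mean"] / m2["ctrl_mean"])
        assert np.allclose(fc1, -fc2)


class TestSignificance:
    def test_reference_table_scan(self):
        """The strict prob > 0.95 rule agrees with a brute-force scan of the
        packaged table; rows printed as exactly 0.95 are NOT significant."""
        ref = load_te_reference_table()
        from oxichrom.tediff import TEResult

        results = [
            TEResult(r.family, r.ctrl_mean, r.kd_mean, r.log2fc, prob=r.prob)
            for r in ref.itertuples(index=False)
        ]
        flagged = {r.family for r in significance_filter(results) if r.significant}
        brute = {r.family for r in ref.itertuples(index=False) if r.prob > 0.95}
        assert flagged == brute
        assert "ERV1" not in flagged  # printed 0.95 exactly
        boundary = [r for r in results if r.family == "ERV1"]
        assert not significance_filter(boundary)[0].significant

    def test_prob_one_significant_missing_prob_rejected(self):
        from oxichrom.tediff import TEResult

        ok = TEResult("x", 1, 2, 1.0, prob=1.0)
        assert significance_filter([ok])[0].significant
        with pytest.raises(ValidationError, match="probability"):
            significance_filter([TEResult("y", 1, 2, 1.0)])


class TestPermutationProb:
    def test_planted_change_detected(self, rng):
        base = rng.integers(500, 5000, 30).astype(float)
        noise = lambda: rng.normal(1, 0.02, 30)
        counts = {
            "c1": base * noise(), "c2": base * noise(),
            "k1": base * noise(), "k2": base * noise(),
        }
        for s in ("k1", "k2"):
            counts[s][0] *= 4.0  # one family, 4x change, tight replicates
        tab = _table(counts)
        probs = prob_from_permutation(tab, n_perm=400, seed=11)
        assert probs.iloc[0] > 0.95

    def test_identical_counts_give_zero(self):
        col = [100.0, 500.0, 900.0]
        tab = _table({"c1": col, "c2": col, "k1": col, "k2": col})
        probs = prob_from_permutation(tab, n_perm=100, seed=3)
        assert (probs == 0.0).all()

    def test_null_probs_spread_over_unit_interval(self):
        """On exchangeable data the surrogate probabilities should be spread
        roughly uniformly, not piled near 0 or 1."""
        vals = []
        for seed in range(20):
            tab, _truth = simulate_te_table(
                SimConfig(seed=seed, te_planted={}, te_n_families=20)
            )
            vals.append(prob_from_permutation(tab, n_perm=200, seed=seed).to_numpy())
        vals = np.concatenate(vals)
        assert 0.35 < np.mean(vals) < 0.65
        assert np.mean(vals < 0.5) == pytest.approx(0.5, abs=0.15)

    def test_deterministic_given_seed(self, rng):
        counts = rng.integers(10, 1000, (15, 4)).astype(float)
        tab = _table({s: counts[:, i] for i, s in enumerate("abcd")})
        p1 = prob_from_permutation(tab, n_perm=100, seed=9)
        p2 = prob_from_permutation(tab, n_perm=100, seed=9)
        assert p1.equals(p2)


def test_te_results_end_to_end(rng):
    tab, truth = simulate_te_table(SimConfig(seed=3))
    probs = prob_from_permutation(tab, n_perm=200, seed=3)
    results = te_results(tab, probs=probs)
    by_family = {r.family: r for r in results}
    for fam, lfc in truth.items():
        if lfc != 0:
            assert by_family[fam].log2fc == pytest.approx(lfc, abs=0.5)
            assert by_family[fam].significant
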