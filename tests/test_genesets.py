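"""Gene-set rank tests, length-residual correction, GMT/TSV parsing."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from riboten import (
    GeneSet,
    GroupDef,
    SimulationConfig,
    geneset_percent_summary,
    length_corrected_test,
    load_genesets,
    mwu_geneset_test,
    simulate_experiment,
    te_analysis,
)
from riboten.errors import DataError


def _values(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))], dtype=float)


def enumeration_p(set_values, other_values):
    """Exact one-sided ('less') p by enumerating all rank assignments."""
    pooled = sorted(set_values + other_values)
    observed = sum(pooled.index(v) + 1 for v in set_values)
    n = len(set_values)
    sums = [sum(c) + n for c in combinations(range(len(pooled)), n)]
    return sum(s <= observed for s in sums) / len(sums)


class TestMWU:
    def test_exact_p_on_three_vs_three(self):
        values = _values([1, 2, 3, 4, 5, 6])
        gs = GeneSet.from_ids("low", ["g0", "g1", "g2"])
        res = mwu_geneset_test(values, gs, alternative="less")
        assert res.exact
        assert res.p == pytest.approx(1 / 20)
        assert res.p == pytest.approx(enumeration_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_on_random_data(self, rng):
        vals = list(np.round(rng.normal(size=10), 6))
        values = _values(vals)
        gs = GeneSet.from_ids("s", ["g0", "g1", "g2", "g3"])
        res = mwu_geneset_test(values, gs, alternative="less")
        assert res.p == pytest.approx(enumeration_p(vals[:4], vals[4:]), abs=1e-12)

    def test_symmetric_null_p_near_half(self):
        values = _values([1, 2, 3, 4, 1, 2, 3, 4, 1, 2, 3, 4])
        gs = GeneSet.from_ids("s", [f"g{i}" for i in range(4)])
        res = mwu_geneset_test(values, gs, alternative="less")
        assert res.p == pytest.approx(0.5, abs=0.1)

    def test_exact_and_asymptotic_agree(self, rng):
        # tie-free data around the exactness cutoff sizes
        for n_in, n_out in [(8, 12), (10, 10), (12, 8)]:
            vals = list(rng.normal(size=n_in + n_out))
            values = _values(vals)
            gs = GeneSet.from_ids("s", [f"g{i}" for i in range(n_in)])
            exact = mwu_geneset_test(values, gs, "less")
            assert exact.exact
            # force the normal approximation through scipy directly
            from scipy.stats import mannwhitneyu

            approx = mannwhitneyu(
                vals[:n_in], vals[n_in:], alternative="less", method="asymptotic"
            ).pvalue
            assert abs(exact.p - approx) < 0.01

    def test_null_rejection_rate_calibrated(self, rng):
        values = _values(rng.normal(size=2000))
        genes = list(values.index)
        rejections = 0
        n_sets = 1000
        for _ in range(n_sets):
            members = rng.choice(genes, size=30, replace=False)
            res = mwu_geneset_test(values, GeneSet.from_ids("s", members), "less")
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_sets <= 0.07

    def test_set_outside_universe_is_error(self):
        values = _values([1, 2, 3, 4])
        with pytest.raises(DataError, match="gX"):
            mwu_geneset_test(values, GeneSet.from_ids("s", ["gX"]), "less")

    def test_explicit_complement_background(self):
        values = _values([1, 2, 3, 10, 11, 12, 5, 6])
        gs = GeneSet.from_ids("s", ["g0", "g1", "g2"])
        full = mwu_geneset_test(values, gs, "less")
        other_only = mwu_geneset_test(values, gs, "less", complement=["g6", "g7"])
        assert other_only.n_out == 2
        assert other_only.p != full.p


class TestLengthCorrection:
    def test_perfect_length_trend_leaves_null_residuals(self):
        L = _values(np.geomspace(200, 5000, 100))
        dte = pd.Series(0.4 * np.log10(L) - 1.0, index=L.index)
        shortest = list(L.sort_values().index[:10])
        res = length_corrected_test(dte, L, [GeneSet.from_ids("short", shortest)])
        assert np.allclose(res.residuals, 0.0, atol=1e-12)
        assert res.tests["short"].p == pytest.approx(0.5, abs=0.1)

    def test_slope_matches_normal_equations_oracle(self, rng):
        L = _values(rng.integers(150, 6000, 200))
        dte = pd.Series(rng.normal(size=200), index=L.index)
        res = length_corrected_test(dte, L, [])
        x = np.log10(L.to_numpy(float))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ dte.to_numpy())
        assert res.slope == pytest.approx(beta[0], abs=1e-10)
        assert res.intercept == pytest.approx(beta[1], abs=1e-10)
        assert abs(res.residuals.sum()) < 1e-9 * np.abs(dte).sum()

    def test_corrected_test_isolates_excess_shift(self):
        """A short-ORF set with only the length-mediated effect loses
        significance after correction; an extra planted shift survives it."""
        for shift, expect_significant in [(0.0, False), (-0.3, True)]:
            cfg = SimulationConfig(
                n_genes=4000,
                seed=31,
                group_defs=(
                    GroupDef("s", quantile_range=(0.0, 0.05), size=150,
                             extra_shift_log2=shift),
                ),
            )
            ann, truth, counts = simulate_experiment(cfg)
            table = te_analysis(counts).table
            gs = GeneSet.from_ids("s", truth.groups["s"])
            raw = mwu_geneset_test(table.dte_log2, gs, "less")
            assert raw.p < 1e-6  # short sets always look shifted before correction
            corrected = length_corrected_test(
                table.dte_log2, ann.orf_lengths()[table.index], [gs]
            ).tests["s"]
            if expect_significant:
                assert corrected.p < 1e-3
            else:
                assert corrected.p > 0.01


class TestSummaryAndIO:
    def test_undersized_set_skipped(self, rng):
        values = _values(rng.normal(size=100))
        L = _values(rng.integers(150, 5000, 100))
        small = GeneSet.from_ids("small", [f"g{i}" for i in range(20)])
        big = GeneSet.from_ids("big", [f"g{i}" for i in range(40)])
        summary, skipped = geneset_percent_summary(values, L, [small, big])
        assert skipped == ["small"]
        assert list(summary["set"]) == ["big"]

    def test_constant_values_summarized_exactly(self):
        values = _values(np.full(30, -12.5))
        L = _values(np.arange(30) + 200.0)
        gs = GeneSet.from_ids("s", list(values.index))
        summary, _ = geneset_percent_summary(values, L, [gs], min_size=21)
        assert summary.loc[0, "median_pct"] == -12.5
        assert summary.loc[0, "mean_pct"] == -12.5

    def test_matches_group_by_oracle(self, rng):
        values = _values(rng.normal(size=400))
        L = _values(rng.integers(150, 8000, 400))
        sets = [
            GeneSet.from_ids(f"s{k}", rng.choice(list(values.index), 30, replace=False))
            for k in range(30)
        ]
        summary, skipped = geneset_percent_summary(values, L, sets)
        assert not skipped
        assert len(summary) == 30
        for _, row in summary.iterrows():
            members = [g for g in values.index if g in
                       next(s for s in sets if s.name == row["set"]).members]
            assert row["median_pct"] == pytest.approx(np.median(values[members]))
            assert row["n"] == len(members)
        assert summary.median_length.is_monotonic_increasing

    def test_gmt_parsing(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("RP\tribosomal proteins\tg1\tg2\nMRP\tdesc\tg3\tg4\tg5\n")
        sets = load_genesets(p)
        assert [s.name for s in sets] == ["RP", "MRP"]
        assert sets[0].members == frozenset({"g1", "g2"})

    def test_two_column_tsv_parsing(self, tmp_path):
        p = tmp_path / "groups.tsv"
        p.write_text("gene_id\tgroup\ng1\tclosed_loop\ng2\tclosed_loop\ng3\tother\n")
        sets = {s.name: s for s in load_genesets(p)}
        assert sets["closed_loop"].members == frozenset({"g1", "g2"})
        assert sets["other"].members == frozenset({"g3"})

    def test_duplicate_member_deduplicated_with_warning(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("RP\tdesc\tg1\tg1\tg2\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = load_genesets(p)
        assert sets[0].members == frozenset({"g1", "g2"})

    def test_malformed_gmt_line_is_hard_error(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("RP\tonly-two-fields\n")
        with pytest.raises(DataError, match=":1"):
            load_genesets(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("")
        assert load_genesets(p) == []
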