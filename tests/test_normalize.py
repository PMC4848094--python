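"""Median-of-ratios normalization, pseudocount rule, TE and dTE tables."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboten import (
    CountMatrix,
    MedianOfRatiosNormalizer,
    SimulationConfig,
    apply_pseudocount,
    compute_delta_te,
    compute_te,
    simulate_experiment,
    size_factors,
    te_analysis,
)
from riboten.errors import DataError

LIBS4 = ["FP:WT:rep1", "FP:WT:rep2", "FP:mut:rep1", "FP:mut:rep2"]


def brute_force_size_factors(df: pd.DataFrame) -> list[float]:
    """Textbook median-of-ratios, written independently with plain loops."""
    usable = [g for g, row in df.iterrows() if all(v > 0 for v in row)]
    refs = {
        g: math.prod(float(v) for v in df.loc[g]) ** (1.0 / df.shape[1])
        for g in usable
    }
    return [
        statistics.median(float(df.loc[g, lib]) / refs[g] for g in usable)
        for lib in df.columns
    ]


class TestSizeFactors:
    def test_identical_libraries_get_unit_factors(self):
        df = pd.DataFrame({lib: [10, 20, 5] for lib in LIBS4}, index=list("abc"))
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_library_forced_values(self):
        df = pd.DataFrame(
            {"FP:WT:rep1": [10, 4, 7], "FP:WT:rep2": [20, 8, 14]}, index=list("abc")
        )
        s = size_factors(df)
        assert np.allclose(s, [1 / math.sqrt(2), math.sqrt(2)])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            df = pd.DataFrame(
                rng.integers(0, 200, size=(50, 4)),
                index=[f"g{i}" for i in range(50)],
                columns=LIBS4,
            )
            if not ((df > 0).all(axis=1)).any():
                continue
            assert np.allclose(
                size_factors(df), brute_force_size_factors(df), atol=1e-12, rtol=0
            )

    @given(c=st.integers(2, 50))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_scale_equivariance(self, c):
        base = pd.DataFrame(
            {"FP:WT:rep1": [10, 4, 7, 9], "FP:WT:rep2": [3, 5, 8, 2]},
            index=list("abcd"),
        )
        scaled = base.copy()
        scaled["FP:WT:rep2"] *= c
        s0, s1 = size_factors(base), size_factors(scaled)
        # factors are defined up to a common scale, so equivariance is a
        # statement about factor ratios
        assert np.isclose(
            (s1["FP:WT:rep2"] / s1["FP:WT:rep1"]),
            c * s0["FP:WT:rep2"] / s0["FP:WT:rep1"],
        )

    def test_normalization_removes_depth(self):
        df = pd.DataFrame(
            {"FP:WT:rep1": [10, 40, 70], "FP:WT:rep2": [20, 80, 140]},
            index=list("abc"),
        )
        norm = MedianOfRatiosNormalizer().fit_transform(df)
        assert np.allclose(norm["FP:WT:rep1"], norm["FP:WT:rep2"], rtol=1e-9)

    def test_all_zero_overlap_is_hard_error(self):
        df = pd.DataFrame({"FP:WT:rep1": [5, 0], "FP:WT:rep2": [0, 5]}, index=list("ab"))
        with pytest.raises(DataError, match="pseudocount"):
            size_factors(df)


class TestPseudocount:
    def test_partial_detection_gets_pseudocount(self):
        df = pd.DataFrame([[0, 3, 5, 0]], index=["g1"], columns=LIBS4)
        out, flags = apply_pseudocount(CountMatrix(df))
        assert list(out.counts.loc["g1"]) == [1, 4, 6, 1]
        assert flags["g1"] == "pseudocounted"

    def test_fully_detected_gene_unchanged(self):
        df = pd.DataFrame([[2, 3, 4, 5]], index=["g1"], columns=LIBS4)
        out, flags = apply_pseudocount(CountMatrix(df))
        assert list(out.counts.loc["g1"]) == [2, 3, 4, 5]
        assert flags["g1"] == ""

    def test_all_zero_gene_flagged_excluded(self):
        df = pd.DataFrame([[0, 0, 0, 0]], index=["g1"], columns=LIBS4)
        out, flags = apply_pseudocount(CountMatrix(df))
        assert list(out.counts.loc["g1"]) == [0, 0, 0, 0]
        assert flags["g1"] == "excluded_all_zero"

    def test_single_read_gene_unchanged(self):
        # max must exceed 1 for the rule to fire
        df = pd.DataFrame([[0, 1, 0, 0]], index=["g1"], columns=LIBS4)
        out, _ = apply_pseudocount(CountMatrix(df))
        assert list(out.counts.loc["g1"]) == [0, 1, 0, 0]


class TestTE:
    def test_identical_fp_and_total_give_unit_te(self):
        norm = pd.DataFrame({"r1": [3.0, 7.0], "r2": [4.0, 1.0]}, index=list("ab"))
        assert np.allclose(compute_te(norm, norm), 1.0)

    def test_direct_ratio(self):
        fp = pd.DataFrame({"r1": [20.0]}, index=["g"])
        total = pd.DataFrame({"r1": [10.0]}, index=["g"])
        assert compute_te(fp, total)["g"] == 2.0

    def test_replicate_geometric_mean(self):
        fp = pd.DataFrame({"r1": [1.0], "r2": [4.0]}, index=["g"])
        total = pd.DataFrame({"r1": [1.0], "r2": [1.0]}, index=["g"])
        assert compute_te(fp, total)["g"] == pytest.approx(2.0)
        assert compute_te(fp, total, "arithmetic")["g"] == pytest.approx(2.5)

    def test_zero_total_flags_undefined(self):
        fp = pd.DataFrame({"r1": [5.0]}, index=["g"])
        total = pd.DataFrame({"r1": [0.0]}, index=["g"])
        assert np.isnan(compute_te(fp, total)["g"])

    def test_delta_te_identity_and_halving(self):
        te_wt = pd.Series({"same": 2.0, "halved": 2.0})
        te_mut = pd.Series({"same": 2.0, "halved": 1.0})
        table = compute_delta_te(te_wt, te_mut)
        assert table.loc["same", "dte_log2"] == 0.0
        assert table.loc["same", "dte_percent"] == 0.0
        assert table.loc["halved", "dte_log2"] == -1.0
        assert table.loc["halved", "dte_percent"] == -50.0

    def test_log2_and_percent_consistent(self, small_experiment):
        *_, counts = small_experiment
        table = te_analysis(counts, min_pooled=32).table
        assert np.allclose(
            table.dte_percent, 100 * (np.exp2(table.dte_log2) - 1), rtol=1e-9
        )

    def test_end_to_end_matches_independent_recomputation(self, small_experiment):
        """Full te_analysis equals a from-scratch pipeline written inline."""
        *_, counts = small_experiment
        result = te_analysis(counts, min_pooled=64)
        df = counts.counts
        # independent path: per-assay size factors, filter, per-replicate
        # ratios, geometric mean, log ratios
        retained = df.index[df.sum(axis=1) >= 64]
        fp_cols = [c for c in df.columns if c.startswith("FP:")]
        tot_cols = [c for c in df.columns if c.startswith("total:")]
        s = pd.concat(
            [pd.Series(brute_force_size_factors(df[cols]), index=cols)
             for cols in (fp_cols, tot_cols)]
        )
        norm = df.loc[retained] / s
        te = {}
        for cond in ("WT", "mut"):
            r1 = norm[f"FP:{cond}:rep1"] / norm[f"total:{cond}:rep1"]
            r2 = norm[f"FP:{cond}:rep2"] / norm[f"total:{cond}:rep2"]
            te[cond] = np.sqrt(r1 * r2)
        expected_dte = np.log2(te["mut"] / te["WT"]).dropna()
        common = result.table.index
        assert np.allclose(result.table.dte_log2, expected_dte[common], atol=1e-10)


class TestNullAndReplicates:
    def test_null_simulation_mean_dte_near_zero(self):
        cfg = SimulationConfig(
            n_genes=4000, dte_length_slope=0.0, dte_sigma=0.0, seed=21
        )
        _, _, counts = simulate_experiment(cfg)
        table = te_analysis(counts).table
        assert abs(table.dte_log2.mean()) < 0.02

    def test_replicate_pairs_positively_correlated(self):
        # two disjoint replicate pairs of the same mutant, planted effect sd 0.5
        from scipy import stats

        cfg = SimulationConfig(
            n_genes=4000, dte_length_slope=0.0, dte_sigma=0.5, n_replicates=4, seed=22
        )
        _, _, counts = simulate_experiment(cfg)

        def pair(reps):
            cols = [l.id for l in counts.libraries if l.replicate in reps]
            return te_analysis(CountMatrix(counts.counts[cols])).table

        t1, t2 = pair(("rep1", "rep2")), pair(("rep3", "rep4"))
        common = t1.index.intersection(t2.index)
        r = stats.pearsonr(t1.dte_log2[common], t2.dte_log2[common]).statistic
        assert r > 0.5
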