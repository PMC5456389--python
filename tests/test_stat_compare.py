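"""Statistical engines against enumeration oracles, plus suite plumbing."""

import numpy as np
import pandas as pd
import pytest

from denpipe.den_core import GenePartition
from denpipe.stat_compare import (
    AnalysisConfig,
    FeatureBundle,
    chi_squared_table,
    chromosome_updown_tests,
    fisher_2x2,
    ks_two_sample,
    rank_sum_test,
    results_frame,
    run_full_analysis,
    signed_rank_paired,
    spearman_corr,
)
from oracles import (
    chi2_stat_direct,
    fisher_exact_p,
    ks_D_sweep,
    ranksum_exact_p,
    signedrank_exact_p,
    spearman_rho_direct,
)


def random_tie_free(rng, n1, n2):
    pooled = rng.permutation(np.arange(1, 200, dtype=float))[: n1 + n2]
    return pooled[:n1], pooled[n1:]


class TestRankSum:
    def test_separated_triplets_exact_p(self):
        result = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert result.p_value == pytest.approx(0.1, abs=1e-12)
        assert result.direction == "low_greater"
        assert "exact" in result.flags

    def test_identical_samples_are_null(self):
        result = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.p_value >= 0.99
        assert result.direction == "none"

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_regime_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 7))
        n2 = int(rng.integers(2, 13 - n1))
        a, b = random_tie_free(rng, n1, n2)
        result = rank_sum_test(a, b)
        assert result.p_value == pytest.approx(ranksum_exact_p(a, b), abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=8), rng.normal(size=11) + 0.5
        fwd = rank_sum_test(a, b)
        rev = rank_sum_test(b, a)
        assert fwd.p_value == pytest.approx(rev.p_value, rel=1e-12)
        assert {fwd.direction, rev.direction} == {"high_greater", "low_greater"}

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSignedRank:
    def test_identical_pairs_give_p_one(self):
        result = signed_rank_paired([1, 2, 3], [1, 2, 3])
        assert result.p_value == 1.0
        assert result.direction == "none"
        assert "all_zero" in result.flags

    def test_all_positive_differences_n6(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        result = signed_rank_paired(x + np.array([0.5, 0.6, 0.7, 0.8, 0.9, 1.0]), x)
        assert result.p_value == pytest.approx(2 / 64, abs=1e-12)
        assert result.direction == "high_greater"

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_regime_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 12))
        x = rng.permutation(np.arange(1, 100, dtype=float))[:n]
        y = x + rng.choice([-1, 1], size=n) * rng.permutation(
            np.arange(1, 50, dtype=float))[:n] / 100.0
        result = signed_rank_paired(x, y)
        assert result.p_value == pytest.approx(signedrank_exact_p(x, y), abs=1e-10)


class TestChiSquared:
    def test_perfect_independence(self):
        result = chi_squared_table([[10, 10], [10, 10]])
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_df_for_2x7(self):
        table = np.ones((7, 2)) * 10
        assert chi_squared_table(table).summaries["df"] == 6

    @pytest.mark.parametrize("seed", range(8))
    def test_statistic_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 60, size=(2, 4))
        result = chi_squared_table(table)
        stat, df = chi2_stat_direct(table)
        assert result.statistic == pytest.approx(stat, abs=1e-10)
        assert result.summaries["df"] == df

    def test_invariant_under_permutations(self):
        rng = np.random.default_rng(1)
        table = rng.integers(1, 40, size=(3, 4))
        base = chi_squared_table(table).statistic
        assert chi_squared_table(table[::-1]).statistic == pytest.approx(base)
        assert chi_squared_table(table[:, ::-1]).statistic == pytest.approx(base)

    def test_zero_margin_names_the_margin(self):
        with pytest.raises(ValueError, match="row 1"):
            chi_squared_table([[5, 5], [0, 0]])
        with pytest.raises(ValueError, match="column 0"):
            chi_squared_table([[0, 5], [0, 5]])

    def test_low_expected_count_flagged(self):
        result = chi_squared_table([[2, 30], [3, 40]])
        assert "low_expected" in result.flags


class TestKs:
    def test_identity_and_separation(self):
        same = np.arange(10.0)
        assert ks_two_sample(same, same).statistic == 0.0
        low, high = np.arange(5.0), np.arange(10.0, 16.0)
        assert ks_two_sample(low, high).statistic == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_D_matches_ecdf_sweep(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(5, 40)))
        b = rng.normal(0.3, 1.2, size=int(rng.integers(5, 40)))
        result = ks_two_sample(a, b)
        assert result.statistic == pytest.approx(ks_D_sweep(a.tolist(), b.tolist()),
                                                 abs=1e-10)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_zero_margin_degenerate(self):
        result = fisher_2x2([[0, 0], [3, 7]])
        assert result.p_value == 1.0
        assert "degenerate_margin" in result.flags

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_rational_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 25, size=(2, 2))
        result = fisher_2x2(table)
        assert result.p_value == pytest.approx(fisher_exact_p(table.tolist()),
                                               abs=1e-10)

    def test_direction_follows_proportions(self):
        assert fisher_2x2([[9, 1], [1, 9]]).direction == "high_greater"
        assert fisher_2x2([[1, 9], [9, 1]]).direction == "low_greater"

    def test_underflowed_p_is_floored_not_zero(self):
        result = fisher_2x2([[100000, 1000], [1000, 100000]])
        assert 0.0 < result.p_value
        assert "p_floor" in result.flags


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_corr(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman_corr(x, -x - 5).statistic == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_tied_data_matches_rank_then_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 4, size=30).astype(float)
        result = spearman_corr(x, y)
        assert result.statistic == pytest.approx(
            spearman_rho_direct(x.tolist(), y.tolist()), abs=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=25), rng.normal(size=25)
        base = spearman_corr(x, y).statistic
        assert spearman_corr(np.exp(x), y).statistic == pytest.approx(base)
        assert spearman_corr(x, y ** 3).statistic == pytest.approx(base)

    def test_zero_rank_variance_flagged(self):
        result = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(result.statistic)
        assert "zero_variance" in result.flags


class TestResultsFrame:
    def test_bh_column_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(0)
        results = [rank_sum_test(rng.normal(size=8), rng.normal(size=8),
                                 feature=f"f{i}") for i in range(20)]
        frame = results_frame(results)
        assert (frame["p_adjusted_bh"] >= frame["p_value"] - 1e-15).all()
        ordered = frame.sort_values("p_value")
        assert ordered["p_adjusted_bh"].is_monotonic_increasing

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            results_frame([])


class TestRunFullAnalysis:
    def _inputs(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i:02d}" for i in range(40)]
        counts = pd.DataFrame(
            {"up_count": rng.integers(0, 20, 40),
             "down_count": rng.integers(0, 20, 40), "n_samples": 30},
            index=pd.Index(genes, name="unit_id"))
        partitions = {
            d: GenePartition(
                direction=d, high_set=frozenset(genes[:6]),
                low_set=frozenset(genes[6:]))
            for d in ("up", "down")
        }
        tes = pd.Series(rng.random(40), index=genes)
        return counts, partitions, tes

    def test_only_configured_comparisons_emitted(self):
        counts, partitions, tes = self._inputs()
        bundle = FeatureBundle(tes=tes)
        results = run_full_analysis(counts, partitions, bundle,
                                    AnalysisConfig(enabled=frozenset({"tes"})))
        assert {r.feature for r in results} == {"tes"}
        assert len(results) == 2  # one per direction

    def test_disjoint_feature_table_is_skipped_not_fatal(self):
        counts, partitions, _ = self._inputs()
        rng = np.random.default_rng(1)
        orphan_tes = pd.Series(rng.random(5), index=[f"X{i}" for i in range(5)])
        results = run_full_analysis(counts, partitions,
                                    FeatureBundle(tes=orphan_tes))
        assert [r for r in results if r.feature == "tes"] == []

    def test_direction_matches_summary_medians(self):
        counts, partitions, tes = self._inputs()
        results = run_full_analysis(counts, partitions, FeatureBundle(tes=tes),
                                    AnalysisConfig(enabled=frozenset({"tes"})))
        for r in results:
            if r.direction == "high_greater":
                assert r.summaries["median_high"] >= r.summaries["median_low"]
            elif r.direction == "low_greater":
                assert r.summaries["median_high"] <= r.summaries["median_low"]


class TestChromosomeUpDown:
    def test_biased_chromosome_detected_paired(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(30):  # strongly up-biased chromosome
            rows.append(("Yg%d" % i, "chrY", int(rng.integers(5, 15)),
                         int(rng.integers(0, 3))))
        for i in range(30):  # balanced chromosome
            c = int(rng.integers(0, 10))
            rows.append(("Ag%d" % i, "chr1", c, c))
        table = pd.DataFrame(rows, columns=["gene_id", "chromosome",
                                            "up_count", "down_count"])
        results = {r.feature: r for r in chromosome_updown_tests(table)}
        y = results["up_vs_down_den_chrY"]
        assert y.direction == "high_greater"
        assert y.p_value < 1e-4
        assert results["up_vs_down_den_chr1"].p_value == 1.0
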