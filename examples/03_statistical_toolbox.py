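"""The nonparametric tests used by the comparison suite, stand-alone.

Small samples are tested exactly (enumeration-equivalent p-values); the
same functions switch to standard approximations for larger inputs.
"""

from denpipe.stat_compare import (
    chi_squared_table,
    fisher_2x2,
    rank_sum_test,
    signed_rank_paired,
    spearman_corr,
)

# fully separated triplets: the most extreme of C(6,3)=20 assignments in
# either tail, hence exact two-sided p = 2/20
r = rank_sum_test([1, 2, 3], [4, 5, 6])
print(f"rank-sum   p={r.p_value:.4f} ({'exact' if 'exact' in r.flags else 'approx'})")

# six positive paired differences: 2 of the 2^6 sign patterns are as extreme
r = signed_rank_paired([1.5, 2.6, 3.7, 4.9, 6.2, 7.8], [1, 2, 3, 4, 5, 6])
print(f"signed-rank p={r.p_value:.5f} direction={r.direction}")

# disease-SNP style 2x2: 90/10 vs 60/40 outcome split
r = fisher_2x2([[90, 10], [60, 40]])
print(f"fisher     p={r.p_value:.3g} odds_ratio={r.statistic:.2f} "
      f"direction={r.direction}")

# a 7x2 stage-by-group table, as in the developmental-stage comparison
table = [[20, 35], [18, 30], [25, 24], [12, 11], [10, 9], [8, 10], [30, 12]]
r = chi_squared_table(table)
print(f"chi2       stat={r.statistic:.2f} df={r.summaries['df']} p={r.p_value:.3g}")

# Spearman handles ties by average ranks
r = spearman_corr([1, 2, 2, 3, 5, 8], [10, 12, 11, 15, 14, 30])
print(f"spearman   rho={r.statistic:.3f} p={r.p_value:.3f}")
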