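"""Group comparisons between frequently and rarely regulated gene sets.

Wraps the nonparametric tests used throughout the analysis -- rank-sum and
signed-rank Wilcoxon tests, Pearson chi-squared, two-sample
Kolmogorov-Smirnov, Fisher's exact test and Spearman correlation -- in a
uniform :class:`ComparisonResult` record, and orchestrates the full suite
of comparisons over every feature axis.  Small tie-free samples are tested
exactly (enumeration-equivalent p-values); larger ones use the standard
normal/t approximations with tie and continuity corrections.

Raw p-values are reported as-is (no correction is applied to the headline
numbers) but a Benjamini-Hochberg adjusted column is always emitted
alongside for transparency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .den_core import GenePartition, top_last_n
from .gene_features import (
    SUBCELLULAR_CLASSES,
    chrom_pair_distances,
)

logger = logging.getLogger(__name__)

#: sample-size bound below which tie-free rank tests are computed exactly
EXACT_LIMIT = 12

#: smallest positive double, reported instead of an underflowed p of 0
P_FLOOR = float(np.nextafter(0.0, 1.0))

__all__ = [
    "ComparisonResult",
    "FeatureBundle",
    "AnalysisConfig",
    "rank_sum_test",
    "signed_rank_paired",
    "chi_squared_table",
    "ks_two_sample",
    "fisher_2x2",
    "spearman_corr",
    "run_full_analysis",
    "chromosome_updown_tests",
    "results_frame",
]


@dataclass
class ComparisonResult:
    """One statistical comparison between two groups (or one correlation)."""

    feature: str
    group_high: str
    group_low: str
    test: str
    statistic: float
    p_value: float
    direction: str  # {high_greater, low_greater, none}
    n_high: int
    n_low: int
    summaries: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.direction not in {"high_greater", "low_greater", "none"}:
            raise ValueError(f"bad direction {self.direction!r}")


def _floor_p(p: float) -> tuple[float, tuple[str, ...]]:
    """Replace an underflowed p of exactly 0 by the smallest positive double."""
    if p == 0.0:
        return P_FLOOR, ("p_floor",)
    return float(p), ()


def _location_direction(a: np.ndarray, b: np.ndarray) -> str:
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        return "high_greater"
    if med_a < med_b:
        return "low_greater"
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_a > mean_b:
        return "high_greater"
    if mean_a < mean_b:
        return "low_greater"
    return "none"


def rank_sum_test(a: Sequence[float], b: Sequence[float], *,
                  feature: str = "", group_high: str = "a",
                  group_low: str = "b") -> ComparisonResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration p-value when the pooled sample is tie-free with at
    most 12 observations; otherwise the normal approximation with tie and
    continuity corrections.  Direction is taken from the group medians.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    p, flags = _floor_p(float(res.pvalue))
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="wilcoxon_ranksum", statistic=float(res.statistic),
        p_value=min(p, 1.0), direction=_location_direction(a, b),
        n_high=a.size, n_low=b.size,
        summaries={"median_high": float(np.median(a)),
                   "median_low": float(np.median(b))},
        flags=flags + (("exact",) if method == "exact" else ()),
    )


def signed_rank_paired(x: Sequence[float], y: Sequence[float], *,
                       feature: str = "", group_high: str = "x",
                       group_low: str = "y") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; with no nonzero difference the result is
    p = 1, direction none.  Exact sign enumeration when at most 12
    tie-free nonzero pairs remain, else the normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("signed-rank test requires paired samples of equal size >= 2")
    diff = x - y
    nonzero = diff[diff != 0]
    base = {"median_diff": float(np.median(diff)), "n_pairs": int(x.size),
            "n_nonzero": int(nonzero.size)}
    if nonzero.size == 0:
        return ComparisonResult(
            feature=feature, group_high=group_high, group_low=group_low,
            test="wilcoxon_signedrank", statistic=0.0, p_value=1.0,
            direction="none", n_high=x.size, n_low=y.size,
            summaries=base, flags=("all_zero",),
        )
    tie_free = np.unique(np.abs(nonzero)).size == nonzero.size
    method = "exact" if (nonzero.size <= EXACT_LIMIT and tie_free) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method=method, correction=(method == "approx"))
    p, flags = _floor_p(float(res.pvalue))
    med = float(np.median(nonzero))
    direction = "high_greater" if med > 0 else ("low_greater" if med < 0 else "none")
    if direction == "none":
        s = float(np.sum(np.sign(nonzero)))
        direction = "high_greater" if s > 0 else ("low_greater" if s < 0 else "none")
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="wilcoxon_signedrank", statistic=float(res.statistic),
        p_value=min(p, 1.0), direction=direction,
        n_high=x.size, n_low=y.size, summaries=base,
        flags=flags + (("exact",) if method == "exact" else ()),
    )


def chi_squared_table(table: Sequence[Sequence[float]], *,
                      feature: str = "", group_high: str = "high",
                      group_low: str = "low") -> ComparisonResult:
    """Pearson chi-squared test of independence on an r x c count table.

    No continuity correction; df = (r-1)(c-1).  A flag is raised when any
    expected count falls below 5.  A zero row/column margin is a hard
    error naming the margin.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-squared needs an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("negative counts in contingency table")
    row_margins = arr.sum(axis=1)
    col_margins = arr.sum(axis=0)
    for i, m in enumerate(row_margins):
        if m == 0:
            raise ValueError(f"degenerate table: row {i} margin is zero")
    for j, m in enumerate(col_margins):
        if m == 0:
            raise ValueError(f"degenerate table: column {j} margin is zero")
    res = stats.chi2_contingency(arr, correction=False)
    flags: tuple[str, ...] = ()
    if (res.expected_freq < 5).any():
        flags = ("low_expected",)
    p, floor_flags = _floor_p(float(res.pvalue))
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="chi_squared", statistic=float(res.statistic),
        p_value=min(p, 1.0), direction="none",
        n_high=int(arr[:, 0].sum()) if arr.shape[1] == 2 else int(arr.sum()),
        n_low=int(arr[:, 1].sum()) if arr.shape[1] == 2 else int(arr.sum()),
        summaries={"df": int(res.dof), "table": arr.astype(int).tolist()},
        flags=flags + floor_flags,
    )


def ks_two_sample(a: Sequence[float], b: Sequence[float], *,
                  feature: str = "", group_high: str = "a",
                  group_low: str = "b") -> ComparisonResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p).

    D is the maximum absolute difference between the two empirical CDFs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    p, flags = _floor_p(float(res.pvalue))
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="ks_two_sample", statistic=float(res.statistic),
        p_value=min(p, 1.0), direction=_location_direction(a, b),
        n_high=a.size, n_low=b.size,
        summaries={"median_high": float(np.median(a)),
                   "median_low": float(np.median(b))},
        flags=flags,
    )


def fisher_2x2(table: Sequence[Sequence[int]], *, feature: str = "",
               group_high: str = "high", group_low: str = "low") -> ComparisonResult:
    """Two-sided Fisher exact test on a 2 x 2 table.

    The p-value sums, over the hypergeometric distribution with the
    observed margins, the probabilities of all tables no more probable
    than the observed one.  Rows are groups (high first), columns are
    outcome / non-outcome.  A zero margin gives p = 1.  The sample odds
    ratio is reported; when a cell is zero a 0.5-continuity-corrected
    version is added for display only.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("fisher_2x2 needs a non-negative 2x2 table")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    summaries: dict = {"table": arr.tolist()}
    if (b * c) > 0:
        summaries["odds_ratio"] = (a * d) / (b * c)
    else:
        summaries["odds_ratio"] = math.inf if a * d > 0 else math.nan
    if 0 in arr:
        summaries["odds_ratio_cc"] = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))

    flags: tuple[str, ...] = ()
    if min(r1, c1) == 0 or r1 == n or c1 == n:
        p = 1.0
        flags = ("degenerate_margin",)
    else:
        lo = max(0, c1 - (c + d))
        hi = min(r1, c1)
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, n, r1, c1)
        p_obs = stats.hypergeom.pmf(a, n, r1, c1)
        included = pmf <= p_obs * (1 + 1e-7)
        p = float(pmf[included].sum())
        if included.all():  # whole support: p is exactly 1 up to rounding
            p = 1.0
        p, flags = _floor_p(min(p, 1.0))
    ratio_high = a / r1 if r1 else math.nan
    ratio_low = c / (c + d) if (c + d) else math.nan
    if math.isnan(ratio_high) or math.isnan(ratio_low) or ratio_high == ratio_low:
        direction = "none"
    else:
        direction = "high_greater" if ratio_high > ratio_low else "low_greater"
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="fisher_exact", statistic=float(summaries["odds_ratio"]),
        p_value=min(p, 1.0), direction=direction,
        n_high=r1, n_low=c + d, summaries=summaries, flags=flags,
    )


def spearman_corr(x: Sequence[float], y: Sequence[float], *,
                  feature: str = "", group_high: str = "x",
                  group_low: str = "y") -> ComparisonResult:
    """Spearman rank correlation (ties averaged, t-approximation p, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires paired samples of size >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return ComparisonResult(
            feature=feature, group_high=group_high, group_low=group_low,
            test="spearman", statistic=float("nan"), p_value=float("nan"),
            direction="none", n_high=x.size, n_low=y.size,
            summaries={}, flags=("zero_variance",),
        )
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p, flags = _floor_p(float(res.pvalue))
    direction = "high_greater" if rho > 0 else ("low_greater" if rho < 0 else "none")
    return ComparisonResult(
        feature=feature, group_high=group_high, group_low=group_low,
        test="spearman", statistic=rho, p_value=min(p, 1.0),
        direction=direction, n_high=x.size, n_low=y.size,
        summaries={"rho": rho}, flags=flags,
    )


# ---------------------------------------------------------------------------
# full-analysis orchestration
# ---------------------------------------------------------------------------

@dataclass
class FeatureBundle:
    """All per-gene feature tables consumed by the comparison suite.

    Any entry may be None, in which case its comparisons are skipped.
    Series are indexed by gene id; ``variants`` is the per-gene SNP
    summary frame from :func:`denpipe.gene_features.variant_summaries`.
    """

    loci: pd.DataFrame | None = None
    tes: pd.Series | None = None
    ees: pd.Series | None = None
    homolog: pd.Series | None = None
    phyletic: pd.Series | None = None
    variants: pd.DataFrame | None = None
    degree: pd.Series | None = None
    subcellular: pd.DataFrame | None = None


@dataclass
class AnalysisConfig:
    """Knobs of the comparison suite."""

    max_pairs: int = 2_000_000      # cap on same-chromosome gene pairs
    seed: int = 0                   # seeds the pair subsampling only
    top_last_n_size: int = 1000     # T/L list size for subcellular classes
    per_chromosome_dsnp: bool = True
    enabled: frozenset[str] | None = None  # None = all comparisons

    def is_enabled(self, name: str) -> bool:
        return self.enabled is None or name in self.enabled


def _split_feature(series: pd.Series, part: GenePartition,
                   feature: str) -> tuple[np.ndarray, np.ndarray] | None:
    values = series.dropna()
    high = values[values.index.isin(part.high_set)].to_numpy(dtype=float)
    low = values[values.index.isin(part.low_set)].to_numpy(dtype=float)
    if high.size < 2 or low.size < 2:
        logger.info("skipping %s for %s: fewer than 2 genes per group",
                    feature, part.direction)
        return None
    return high, low


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(salt,))
               .generate_state(1)[0] % (2**31))


def run_full_analysis(gene_counts: pd.DataFrame,
                      partitions: dict[str, GenePartition],
                      features: FeatureBundle,
                      config: AnalysisConfig | None = None) -> list[ComparisonResult]:
    """Run every configured comparison for both regulation directions.

    For each direction the suite covers: same-chromosome pair distances
    (rank-sum), TES (rank-sum, plus Spearman against DEN), EES
    (chi-squared on stage x group), homolog counts (rank-sum), phyletic
    age (chi-squared), SNP density (KS), disease-SNP fraction (Fisher
    overall, chi-squared per chromosome), interaction degree (rank-sum,
    plus Spearman against DEN), and subcellular classes (chi-squared over
    top/last-N lists).  A comparison with fewer than 2 genes in a group
    is skipped with a logged reason.
    """
    config = config or AnalysisConfig()
    results: list[ComparisonResult] = []
    for salt, (direction, part) in enumerate(sorted(partitions.items())):
        hi_lab, lo_lab = part.high_label, part.low_label
        counts = gene_counts[f"{direction}_count"]

        if features.loci is not None and config.is_enabled("chromosomal_distance"):
            d_hi = chrom_pair_distances(features.loci, part.high_set,
                                        max_pairs=config.max_pairs,
                                        seed=_derived_seed(config.seed, 2 * salt))
            d_lo = chrom_pair_distances(features.loci, part.low_set,
                                        max_pairs=config.max_pairs,
                                        seed=_derived_seed(config.seed, 2 * salt + 1))
            if d_hi.size >= 2 and d_lo.size >= 2:
                results.append(rank_sum_test(
                    d_hi, d_lo, feature="chromosomal_distance",
                    group_high=hi_lab, group_low=lo_lab))
            else:
                logger.info("skipping chromosomal_distance for %s: too few pairs",
                            direction)

        if features.tes is not None:
            if config.is_enabled("tes"):
                split = _split_feature(features.tes, part, "tes")
                if split:
                    results.append(rank_sum_test(
                        *split, feature="tes", group_high=hi_lab, group_low=lo_lab))
            if config.is_enabled("tes_vs_den"):
                merged = pd.concat([features.tes.rename("f"), counts.rename("c")],
                                   axis=1, join="inner").dropna()
                if len(merged) >= 3:
                    results.append(spearman_corr(
                        merged["c"], merged["f"], feature="tes_vs_den",
                        group_high=f"{direction}_den", group_low="tes"))

        if features.ees is not None and config.is_enabled("ees"):
            res = _categorical_comparison(features.ees, part, "ees")
            if res is not None:
                results.append(res)

        if features.homolog is not None and config.is_enabled("homolog_count"):
            split = _split_feature(features.homolog, part, "homolog_count")
            if split:
                results.append(rank_sum_test(
                    *split, feature="homolog_count",
                    group_high=hi_lab, group_low=lo_lab))

        if features.phyletic is not None and config.is_enabled("phyletic_age"):
            res = _categorical_comparison(features.phyletic, part, "phyletic_age")
            if res is not None:
                results.append(res)

        if features.variants is not None:
            var = features.variants.set_index("gene_id") \
                if "gene_id" in features.variants.columns else features.variants
            if config.is_enabled("snp_density"):
                split = _split_feature(var["snp_density"], part, "snp_density")
                if split:
                    results.append(ks_two_sample(
                        *split, feature="snp_density",
                        group_high=hi_lab, group_low=lo_lab))
            if config.is_enabled("dsnp_fraction"):
                results.extend(_dsnp_comparisons(var, part, config))

        if features.degree is not None:
            if config.is_enabled("degree"):
                split = _split_feature(features.degree, part, "degree")
                if split:
                    results.append(rank_sum_test(
                        *split, feature="degree",
                        group_high=hi_lab, group_low=lo_lab))
            if config.is_enabled("degree_vs_den"):
                merged = pd.concat([features.degree.rename("f"), counts.rename("c")],
                                   axis=1, join="inner").dropna()
                if len(merged) >= 3:
                    results.append(spearman_corr(
                        merged["c"], merged["f"], feature="degree_vs_den",
                        group_high=f"{direction}_den", group_low="degree"))

        if features.subcellular is not None and config.is_enabled("subcellular_class"):
            res = _subcellular_comparison(gene_counts, direction,
                                          features.subcellular, config)
            if res is not None:
                results.append(res)
    return results


def _categorical_comparison(series: pd.Series, part: GenePartition,
                            feature: str) -> ComparisonResult | None:
    values = series.dropna()
    high = values[values.index.isin(part.high_set)]
    low = values[values.index.isin(part.low_set)]
    if len(high) < 2 or len(low) < 2:
        logger.info("skipping %s for %s: fewer than 2 genes per group",
                    feature, part.direction)
        return None
    categories = sorted(set(values.unique()))
    table = np.array([
        [int((high == cat).sum()) for cat in categories],
        [int((low == cat).sum()) for cat in categories],
    ]).T  # category x group
    keep = table.sum(axis=1) > 0
    table = table[keep]
    if table.shape[0] < 2:
        logger.info("skipping %s for %s: fewer than 2 populated categories",
                    feature, part.direction)
        return None
    result = chi_squared_table(table, feature=feature,
                               group_high=part.high_label,
                               group_low=part.low_label)
    result.summaries["categories"] = [c for c, k in zip(categories, keep) if k]
    return result


def _dsnp_comparisons(var: pd.DataFrame, part: GenePartition,
                      config: AnalysisConfig) -> list[ComparisonResult]:
    out: list[ComparisonResult] = []
    hi = var[var.index.isin(part.high_set)]
    lo = var[var.index.isin(part.low_set)]
    if len(hi) < 2 or len(lo) < 2:
        logger.info("skipping dsnp_fraction for %s: fewer than 2 genes per group",
                    part.direction)
        return out
    table = [
        [int(hi["dsnp_count"].sum()), int((hi["snp_count"] - hi["dsnp_count"]).sum())],
        [int(lo["dsnp_count"].sum()), int((lo["snp_count"] - lo["dsnp_count"]).sum())],
    ]
    out.append(fisher_2x2(table, feature="dsnp_fraction",
                          group_high=part.high_label, group_low=part.low_label))
    if config.per_chromosome_dsnp and "chromosome" in var.columns:
        agg_hi = hi.groupby("chromosome")[["dsnp_count", "snp_count"]].sum()
        agg_lo = lo.groupby("chromosome")[["dsnp_count", "snp_count"]].sum()
        for chrom in sorted(set(agg_hi.index) | set(agg_lo.index)):
            h = agg_hi.loc[chrom] if chrom in agg_hi.index else None
            l = agg_lo.loc[chrom] if chrom in agg_lo.index else None
            h_d = int(h["dsnp_count"]) if h is not None else 0
            h_s = int(h["snp_count"]) if h is not None else 0
            l_d = int(l["dsnp_count"]) if l is not None else 0
            l_s = int(l["snp_count"]) if l is not None else 0
            t = np.array([[h_d, h_s - h_d], [l_d, l_s - l_d]])
            if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
                logger.info("skipping per-chromosome dsnp test on %s: zero margin",
                            chrom)
                continue
            res = chi_squared_table(t, feature=f"dsnp_fraction_{chrom}",
                                    group_high=part.high_label,
                                    group_low=part.low_label)
            out.append(res)
    return out


def _subcellular_comparison(gene_counts: pd.DataFrame, direction: str,
                            subcellular: pd.DataFrame,
                            config: AnalysisConfig) -> ComparisonResult | None:
    n = min(config.top_last_n_size, len(gene_counts) // 2)
    if n < 2:
        logger.info("skipping subcellular_class for %s: too few genes", direction)
        return None
    top, last = top_last_n(gene_counts, direction, n=n)
    counts = []
    for gene_set in (top, last):
        members = subcellular[subcellular.index.isin(gene_set)]
        counts.append([int(members[c].sum()) for c in SUBCELLULAR_CLASSES])
    table = np.array(counts).T  # class x {top, last}
    keep = table.sum(axis=1) > 0
    table = table[keep]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        logger.info("skipping subcellular_class for %s: degenerate table", direction)
        return None
    result = chi_squared_table(
        table, feature="subcellular_class",
        group_high=f"T{n}{direction[0].upper()}",
        group_low=f"L{n}{direction[0].upper()}")
    result.summaries["classes"] = [c for c, k in zip(SUBCELLULAR_CLASSES, keep) if k]
    return result


def chromosome_updown_tests(chrom_table: pd.DataFrame,
                            min_genes: int = 2) -> list[ComparisonResult]:
    """Paired up-vs-down DEN comparison within each chromosome.

    For every chromosome with at least ``min_genes`` genes, runs the
    signed-rank test on the per-gene (up_count, down_count) pairs; this is
    the comparison that singles out chromosomes whose genes are
    preferentially regulated in one direction (e.g. a Y chromosome biased
    toward up-regulation).
    """
    out: list[ComparisonResult] = []
    for chrom, grp in chrom_table.groupby("chromosome", sort=True):
        if len(grp) < min_genes:
            logger.info("skipping up-vs-down test on %s: fewer than %d genes",
                        chrom, min_genes)
            continue
        out.append(signed_rank_paired(
            grp["up_count"].to_numpy(), grp["down_count"].to_numpy(),
            feature=f"up_vs_down_den_{chrom}", group_high="up", group_low="down"))
    return out


def results_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten results into a table with a Benjamini-Hochberg column.

    The adjusted p-values are computed across all rows with a defined raw
    p; they are reported alongside (never instead of) the raw values.
    """
    if not results:
        raise ValueError("no comparison results to tabulate")
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "group_high": r.group_high,
            "group_low": r.group_low,
            "test": r.test,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "direction": r.direction,
            "n_high": r.n_high,
            "n_low": r.n_low,
            "flags": ";".join(r.flags),
            "summary": _summary_text(r.summaries),
        })
    frame = pd.DataFrame(rows)
    adjusted = np.full(len(frame), np.nan)
    defined = frame["p_value"].notna().to_numpy()
    if defined.any():
        adjusted[defined] = multipletests(
            frame.loc[defined, "p_value"], method="fdr_bh")[1]
    frame["p_adjusted_bh"] = adjusted
    return frame


def _summary_text(summaries: dict) -> str:
    parts = []
    for key, value in sorted(summaries.items()):
        if isinstance(value, float):
            parts.append(f"{key}={value:.6g}")
        else:
            parts.append(f"{key}={value}")
    return "|".join(parts)
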