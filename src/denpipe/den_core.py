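"""Differential expression number (DEN) counting and gene partitioning.

The DEN of a probe (or gene) is the number of treated samples in which its
natural-log fold change crosses a threshold: strictly above ``up_cut`` for
up-regulation events, strictly below ``down_cut`` for down-regulation
events.  The default cutoffs are +/-0.69 (= round(ln 2, 2)), i.e. a
two-fold expression change.  Genes are then ranked by their directional
DEN and split into a frequently regulated top fraction (default 15%,
"up_h"/"down_h") versus the rest ("up_l"/"down_l").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FoldChangeMatrix

logger = logging.getLogger(__name__)

DEFAULT_UP_CUT = 0.69   # round(ln 2, 2): fold change > 2
DEFAULT_DOWN_CUT = -0.69  # fold change < 0.5
DEFAULT_FRACTION = 0.15

__all__ = [
    "Thresholds",
    "GenePartition",
    "count_regulation",
    "aggregate_to_genes",
    "partition_genes",
    "top_last_n",
    "partition_overlap",
    "den_distribution_summary",
    "den_table",
]


@dataclass(frozen=True)
class Thresholds:
    """lnFC cutoffs for calling a regulation event (strict inequalities)."""

    up_cut: float = DEFAULT_UP_CUT
    down_cut: float = DEFAULT_DOWN_CUT

    def __post_init__(self) -> None:
        if not (self.down_cut < 0 < self.up_cut):
            raise ValueError(
                f"thresholds must satisfy down_cut < 0 < up_cut, got "
                f"({self.down_cut}, {self.up_cut})"
            )


@dataclass(frozen=True)
class GenePartition:
    """High/low split of all scored genes for one regulation direction."""

    direction: str                 # "up" or "down"
    high_set: frozenset[str]       # up_h or down_h
    low_set: frozenset[str]        # up_l or down_l
    fraction: float = DEFAULT_FRACTION

    def __post_init__(self) -> None:
        if self.direction not in {"up", "down"}:
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.high_set & self.low_set:
            raise ValueError("high and low sets overlap")

    @property
    def n_genes(self) -> int:
        return len(self.high_set) + len(self.low_set)

    @property
    def high_label(self) -> str:
        return f"{self.direction}_h"

    @property
    def low_label(self) -> str:
        return f"{self.direction}_l"


def count_regulation(matrix: FoldChangeMatrix,
                     thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Count up/down regulation events per probe.

    Returns a frame indexed by probe id with integer columns ``up_count``,
    ``down_count`` and ``n_samples``.  A cell is an up event iff its value
    is strictly greater than ``up_cut`` and a down event iff strictly less
    than ``down_cut``; missing (NaN) cells are events in neither direction.
    """
    thresholds = thresholds or Thresholds()
    values = matrix.values
    with np.errstate(invalid="ignore"):
        up = np.nansum(values > thresholds.up_cut, axis=1).astype(int)
        down = np.nansum(values < thresholds.down_cut, axis=1).astype(int)
    n_samples = matrix.shape[1]
    return pd.DataFrame(
        {"up_count": up, "down_count": down, "n_samples": n_samples},
        index=pd.Index(matrix.probe_ids, name="unit_id"),
    )


def aggregate_to_genes(probe_counts: pd.DataFrame, probe_gene_map: dict[str, str],
                       policy: str = "max") -> pd.DataFrame:
    """Collapse probe-level counts to gene level.

    Probes without a map entry are dropped (their number is logged).  The
    ``up_count`` and ``down_count`` of a gene's probes are combined
    independently under the chosen policy; ``mean`` rounds half-up to an
    integer.  The default ``max`` treats a gene as regulated whenever its
    most responsive probe is.
    """
    if policy not in {"max", "sum", "mean"}:
        raise ValueError(f"unknown aggregation policy {policy!r}")
    genes = probe_counts.index.map(probe_gene_map.get)
    mapped = genes.notna()
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("dropping %d unmapped probes", n_dropped)
    if not mapped.any():
        raise ValueError("no probe in the counts table has a map entry")
    sub = probe_counts.loc[mapped, ["up_count", "down_count"]].copy()
    sub["gene_id"] = genes[mapped]
    grouped = sub.groupby("gene_id")[["up_count", "down_count"]]
    if policy == "max":
        agg = grouped.max()
    elif policy == "sum":
        agg = grouped.sum()
    else:
        agg = np.floor(grouped.mean() + 0.5)  # round half-up
    agg = agg.astype(int)
    agg["n_samples"] = int(probe_counts["n_samples"].iloc[0])
    agg.index.name = "unit_id"
    return agg.sort_index()


def _ranking(gene_counts: pd.DataFrame, direction: str) -> list[str]:
    """Gene ids ranked by directional count descending, ties broken by
    lexicographically ascending gene id (fully deterministic)."""
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be up/down, got {direction!r}")
    col = f"{direction}_count"
    frame = gene_counts[[col]].copy()
    frame["gene_id"] = frame.index.astype(str)
    frame = frame.sort_values([col, "gene_id"], ascending=[False, True],
                              kind="mergesort")
    return list(frame["gene_id"])


def partition_genes(gene_counts: pd.DataFrame, direction: str,
                    fraction: float = DEFAULT_FRACTION) -> GenePartition:
    """Split genes into the top ``fraction`` by directional DEN vs the rest.

    k = floor(fraction * N); the ranking is deterministic (count descending,
    gene id ascending on ties), so repeated runs give identical sets.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if len(gene_counts) < 10:
        raise ValueError("need at least 10 genes to partition")
    order = _ranking(gene_counts, direction)
    k = math.floor(fraction * len(order))
    return GenePartition(
        direction=direction,
        high_set=frozenset(order[:k]),
        low_set=frozenset(order[k:]),
        fraction=fraction,
    )


def top_last_n(gene_counts: pd.DataFrame, direction: str,
               n: int = 1000) -> tuple[frozenset[str], frozenset[str]]:
    """Top-n and last-n genes under the partition ranking (e.g. the
    T1000/L1000 lists exported for external enrichment tools)."""
    if n <= 0:
        raise ValueError("n must be positive")
    order = _ranking(gene_counts, direction)
    if 2 * n > len(order):
        raise ValueError(f"2n = {2 * n} exceeds gene count {len(order)}")
    return frozenset(order[:n]), frozenset(order[-n:])


def top_last_n_ordered(gene_counts: pd.DataFrame, direction: str,
                       n: int = 1000) -> tuple[list[str], list[str]]:
    """Like :func:`top_last_n` but preserving the ranking order, for writing
    gene lists to disk deterministically."""
    if n <= 0:
        raise ValueError("n must be positive")
    order = _ranking(gene_counts, direction)
    if 2 * n > len(order):
        raise ValueError(f"2n = {2 * n} exceeds gene count {len(order)}")
    return order[:n], order[-n:]


def partition_overlap(a: frozenset[str] | set[str],
                      b: frozenset[str] | set[str]) -> dict[str, float]:
    """Exact overlap summary of two gene sets (sizes, intersection, Jaccard)."""
    inter = len(set(a) & set(b))
    union = len(set(a) | set(b))
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": inter,
        "jaccard": inter / union if union else 0.0,
    }


def den_distribution_summary(gene_counts: pd.DataFrame, direction: str,
                             fraction: float = DEFAULT_FRACTION) -> dict:
    """Summarise one direction's DEN distribution.

    Reports a histogram over integer counts, the share of total DEN carried
    by the top ``fraction`` of genes (the heavy-tail signature: under a
    power-law-like distribution a small top fraction holds most events),
    and the sample skewness.
    """
    if gene_counts.empty:
        raise ValueError("empty counts")
    col = f"{direction}_count"
    counts = gene_counts[col].to_numpy()
    order = _ranking(gene_counts, direction)
    k = math.floor(fraction * len(order))
    total = int(counts.sum())
    top_ids = set(order[:k])
    top_sum = int(gene_counts.loc[gene_counts.index.isin(top_ids), col].sum())
    all_zero = total == 0
    share = 0.0 if all_zero else top_sum / total
    hist = np.bincount(counts)
    return {
        "direction": direction,
        "histogram": hist,
        "top_fraction": fraction,
        "top_share": share,
        "skewness": (float(stats.skew(counts))
                     if len(counts) > 2 and np.ptp(counts) > 0 else float("nan")),
        "all_zero": all_zero,
        "n_genes": len(counts),
        "total_den": total,
    }


def den_table(gene_counts: pd.DataFrame, up: GenePartition,
              down: GenePartition) -> pd.DataFrame:
    """Per-gene DEN table with high/low labels for both directions."""
    frame = gene_counts[["up_count", "down_count"]].copy()
    gene_ids = frame.index.astype(str)
    frame["up_label"] = np.where(gene_ids.isin(up.high_set), "up_h", "up_l")
    frame["down_label"] = np.where(gene_ids.isin(down.high_set), "down_h", "down_l")
    frame.index.name = "gene_id"
    return frame.sort_index()
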