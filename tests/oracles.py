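"""Independent brute-force oracles used to verify the statistical engines.

Everything here is deliberately naive -- full enumeration, double loops,
exact rational arithmetic -- and shares no code with the implementations
it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def brute_force_counts(values: np.ndarray, up_cut: float,
                       down_cut: float) -> tuple[np.ndarray, np.ndarray]:
    """Double loop over every cell; NaN counts in neither direction."""
    n_rows, n_cols = values.shape
    up = np.zeros(n_rows, dtype=int)
    down = np.zeros(n_rows, dtype=int)
    for i in range(n_rows):
        for j in range(n_cols):
            v = values[i, j]
            if v != v:  # NaN
                continue
            if v > up_cut:
                up[i] += 1
            elif v < down_cut:
                down[i] += 1
    return up, down


def ranksum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating every group assignment."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    us = [
        sum(idx) - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(1, len(pooled) + 1), n1)
    ]
    total = len(us)
    cdf = sum(1 for u in us if u <= u_obs) / total
    sf = sum(1 for u in us if u >= u_obs) / total
    return min(1.0, 2.0 * min(cdf, sf))


def signedrank_exact_p(x, y) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    absd = sorted(abs(v) for v in d)
    assert len(set(absd)) == len(absd), "oracle requires tie-free differences"
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    w_pos = sum(ranks[abs(v)] for v in d if v > 0)
    n = len(d)
    ws = [
        sum(r for r, s in zip(range(1, n + 1), signs) if s)
        for signs in itertools.product([True, False], repeat=n)
    ]
    total = len(ws)
    cdf = sum(1 for w in ws if w <= w_pos) / total
    sf = sum(1 for w in ws if w >= w_pos) / total
    return min(1.0, 2.0 * min(cdf, sf))


def fisher_exact_p(table) -> float:
    """Two-sided Fisher p by exact-rational hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k: int) -> Fraction:
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                        math.comb(n, c1))

    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs)
    return float(total)


def chi2_stat_direct(table) -> tuple[float, int]:
    """Pearson statistic by the direct sum of (O - E)^2 / E."""
    arr = [list(map(float, row)) for row in table]
    r, c = len(arr), len(arr[0])
    row_sums = [sum(row) for row in arr]
    col_sums = [sum(arr[i][j] for i in range(r)) for j in range(c)]
    total = sum(row_sums)
    stat = 0.0
    for i in range(r):
        for j in range(c):
            expected = row_sums[i] * col_sums[j] / total
            stat += (arr[i][j] - expected) ** 2 / expected
    return stat, (r - 1) * (c - 1)


def ks_D_sweep(a, b) -> float:
    """Max absolute ECDF difference by sweeping every pooled value."""
    a, b = sorted(a), sorted(b)
    best = 0.0
    for v in a + b:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best


def _average_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho_direct(x, y) -> float:
    """Pearson correlation of explicitly computed average ranks."""
    rx = _average_ranks(list(x))
    ry = _average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) *
                    sum((b - my) ** 2 for b in ry))
    return num / den


def brute_force_pair_distances(loci_rows, genes) -> list[float]:
    """All same-chromosome midpoint distances via an explicit double loop."""
    rows = [r for r in loci_rows if r[0] in genes]
    out = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if rows[i][1] != rows[j][1]:
                continue
            mid_i = (rows[i][2] + rows[i][3]) / 2
            mid_j = (rows[j][2] + rows[j][3]) / 2
            out.append(abs(mid_i - mid_j))
    return out
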