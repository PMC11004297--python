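"""Exact small-sample rank-sum test and Pearson chi-squared association test.

The rank-sum engine matters because the study designs are tiny (4 vs 4 and
4 vs 3 mice): asymptotic p-values are meaningless at these sizes, and values
such as 0.02857 = 2/70 and 0.05714 = 2/35 arise only from exact enumeration
of the rank-sum null distribution with tail doubling.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from fractions import Fraction
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import stats as sps

#: largest min(n1, n2) for which the exact enumeration is used
EXACT_MAX_MIN_N = 8


@dataclass(frozen=True)
class RankSumResult:
    """Result of a two-sided unpaired rank-sum (Mann-Whitney U) test."""

    u_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Chi2Result:
    """Result of a Pearson chi-squared test of association."""

    statistic: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def exact_u_distribution(n1: int, n2: int) -> list[int]:
    """Null distribution of the Mann-Whitney U statistic as subset counts.

    Returns ``counts`` of length ``n1*n2 + 1`` where ``counts[u]`` is the
    number of the ``C(n1+n2, n1)`` equally likely rank assignments whose U
    statistic (for the first group) equals ``u``.

    Every interleaving of the two groups corresponds uniquely to a
    nondecreasing sequence ``0 <= j_1 <= ... <= j_{n1} <= n2`` where ``j_k``
    is the number of group-2 values below the k-th group-1 value, and
    ``U = sum j_k``.  ``counts[u]`` is therefore the number of partitions of
    ``u`` into at most ``n1`` parts each at most ``n2``, computed by dynamic
    programming on (parts used, running sum) with parts taken in
    nondecreasing order.  Exact integer arithmetic throughout.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both group sizes must be at least 1")
    max_u = n1 * n2
    # g[i][u]: sequences of i parts, nondecreasing, summing to u, using part
    # values processed so far
    g = [[0] * (max_u + 1) for _ in range(n1 + 1)]
    for i in range(n1 + 1):
        g[i][0] = 1  # all-zero prefix of any length
    for j in range(1, n2 + 1):
        for i in range(1, n1 + 1):
            gi, gprev = g[i], g[i - 1]
            for u in range(j, max_u + 1):
                gi[u] += gprev[u - j]
    counts = g[n1]
    assert sum(counts) == comb(n1 + n2, n1)
    return counts


def exact_rank_sum(xs: Sequence[float], ys: Sequence[float]) -> RankSumResult:
    """Two-sided unpaired rank-sum (Mann-Whitney U) test.

    With ``min(n1, n2) <= 8`` and no ties the p-value is exact: the null
    distribution of U is enumerated by dynamic programming and the two-sided
    p is ``min(1, 2 * min(lower tail, upper tail))``, the observed value
    included in its tail.  Ties or larger samples fall back to mid-ranks
    with the tie-corrected normal approximation, flagged in ``method``.
    """
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")

    n1, n2 = int(xs.size), int(ys.size)
    pooled = np.concatenate([xs, ys])
    has_ties = np.unique(pooled).size < pooled.size

    # Mann-Whitney U of xs: number of (x, y) pairs with y < x, +1/2 per tie
    u1 = float(
        sum(np.count_nonzero(ys < x) + 0.5 * np.count_nonzero(ys == x) for x in xs)
    )

    if not has_ties and min(n1, n2) <= EXACT_MAX_MIN_N:
        counts = exact_u_distribution(n1, n2)
        total = comb(n1 + n2, n1)
        u_obs = int(round(u1))
        lower = sum(counts[: u_obs + 1])
        upper = sum(counts[u_obs:])
        p = min(Fraction(1), 2 * min(Fraction(lower, total), Fraction(upper, total)))
        return RankSumResult(u_statistic=float(u_obs), p_two_sided=float(p), method="exact")

    return _normal_approx(xs, ys, u1)


def _normal_approx(xs: np.ndarray, ys: np.ndarray, u1: float) -> RankSumResult:
    """Mid-rank normal approximation with tie-corrected variance."""
    n1, n2 = xs.size, ys.size
    n = n1 + n2
    pooled = np.concatenate([xs, ys])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every pooled observation identical
        return RankSumResult(u_statistic=u1, p_two_sided=1.0, method="normal-approximation")
    z = (u1 - mu - 0.5 * float(np.sign(u1 - mu))) / sqrt(var)  # continuity corrected
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return RankSumResult(
        u_statistic=u1,
        p_two_sided=max(p, float(np.finfo(float).tiny)),
        method="normal-approximation",
    )


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-squared test of association, no continuity correction.

    ``statistic = sum((observed - expected)^2 / expected)`` with expected
    cell counts from the row/column marginals; ``df = (rows-1)(cols-1)``;
    p from the chi-squared survival function.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("degenerate contingency table: zero row or column marginal")
    expected = np.outer(row, col) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return Chi2Result(statistic=statistic, df=df, p=max(p, float(np.finfo(float).tiny)))
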