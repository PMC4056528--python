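"""Exact and asymptotic nonparametric statistics used across the pipeline.

Exact Mann-Whitney p-values are computed by full enumeration of rank
assignments when both groups are small and no value is shared across groups;
otherwise a tie-corrected normal approximation with continuity correction is
used.  Fisher's exact test sums hypergeometric probabilities no larger than
the observed table's.  Two-sided Mann-Whitney p = 2*min(P_low, P_high),
capped at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special, stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n_a: int
    n_b: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i > b_j) pairs, ties counted 1/2."""
    greater = (a[:, None] > b[None, :]).sum()
    equal = (a[:, None] == b[None, :]).sum()
    return float(greater) + 0.5 * float(equal)


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 8
) -> TestResult:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    Exact p by enumeration of all C(n_a+n_b, n_a) group assignments when both
    group sizes are <= ``exact_limit`` and no value occurs in both groups;
    otherwise normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    u_obs = _u_statistic(a, b)
    cross_ties = bool(set(a.tolist()) & set(b.tolist()))
    if n_a <= exact_limit and n_b <= exact_limit and not cross_ties:
        # No value is shared across groups, so U depends only on which
        # positions of the sorted pooled sample belong to group a.
        n = n_a + n_b
        total = math.comb(n, n_a)
        offset = n_a * (n_a + 1) // 2
        n_low = 0
        n_high = 0
        for combo in combinations(range(1, n + 1), n_a):
            u = sum(combo) - offset
            if u <= u_obs + 1e-12:
                n_low += 1
            if u >= u_obs - 1e-12:
                n_high += 1
        p = min(1.0, 2.0 * min(n_low, n_high) / total)
        return TestResult(u_obs, max(p, 1.0 / total), "exact", n_a, n_b)
    # tie-corrected normal approximation
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = n_a * n_b / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult(u_obs, 1.0, "normal_approx", n_a, n_b)
    z = (u_obs - mu - math.copysign(0.5, u_obs - mu)) / math.sqrt(var)
    if abs(u_obs - mu) <= 0.5:
        z = 0.0
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(u_obs, max(p, np.finfo(float).tiny), "normal_approx",
                      n_a, n_b)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p sums hypergeometric probabilities <= the observed table's probability;
    the reported odds ratio is the conditional MLE.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("table cells must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        # zero-margin table carries no information
        return TestResult(0.0, 1.0, "exact", r1, c + d,
                          extra={"odds_ratio": 1.0, "note": "zero margin"})
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(sps.hypergeom.pmf(a, n, c1, r1))
    p = float(np.sum(pmf[pmf <= p_obs * (1 + 1e-7)]))
    p = min(1.0, max(p, p_obs))
    if p >= 1.0 - 1e-9:  # float round-off when every table qualifies
        p = 1.0
    odds_ratio = float(sps.contingency.odds_ratio(t).statistic)
    return TestResult(float(a), p, "exact", r1, c + d,
                      extra={"odds_ratio": odds_ratio})


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_a - ECDF_b| computed directly; p from the asymptotic
    Kolmogorov distribution at effective n = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(math.sqrt(en) * d))
    p = min(1.0, max(p, np.finfo(float).tiny))
    return TestResult(d, p, "normal_approx", a.size, b.size)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


__all__ = [
    "TestResult",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "ks_two_sample",
    "bh_fdr",
]
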