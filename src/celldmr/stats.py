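"""Exact small-sample statistics shared across the pipeline.

The 2x2 exact test is computed by direct hypergeometric enumeration with
integer arithmetic (no floating-point cancellation), which keeps it valid for
the promoter-scale tables this package produces.  The Mann-Whitney test uses
an exact permutation enumeration for small groups and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # (a*d)/(b*c); inf if only b*c == 0, nan if both products 0
    p_value: float
    degenerate: bool  # a margin was zero (P forced to 1.0)

    def __iter__(self):  # allow ``or_, p = fisher_exact_2x2(...)``
        return iter((self.odds_ratio, self.p_value))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    P is the sum of hypergeometric probabilities (margins fixed) of all tables
    at most as probable as the observed one.  Computed with exact integers.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("fisher_exact_2x2 requires non-negative integer counts")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r, m = a + b, a + c  # row-1 and column-1 margins
    if n == 0 or r == 0 or r == n or m == 0 or m == n:
        return FisherResult(_odds_ratio(a, b, c, d), 1.0, True)
    k_lo, k_hi = max(0, m - (n - r)), min(r, m)
    w_obs = comb(r, a) * comb(n - r, m - a)
    num = sum(
        w for k in range(k_lo, k_hi + 1)
        if (w := comb(r, k) * comb(n - r, m - k)) <= w_obs
    )
    p = float(Fraction(num, comb(n, m)))
    return FisherResult(_odds_ratio(a, b, c, d), min(p, 1.0), False)


def hypergeom_enrichment_p(hits: int, query: int, set_size: int, background: int) -> float:
    """One-sided (over-representation) P: P[X >= hits] for X ~ Hypergeom."""
    if hits > min(query, set_size):
        raise ValueError("hits exceeds min(query size, set size)")
    return float(sps.hypergeom.sf(hits - 1, background, set_size, query))


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact-permutation" or "normal-approximation"
    degenerate: bool  # all pooled values identical


def _rank_u(pooled_ranks: np.ndarray, idx: tuple[int, ...], n1: int) -> float:
    return float(pooled_ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def mann_whitney(x, y, exact_max_n: int = 12) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For combined n <= ``exact_max_n`` the P-value is the exact permutation
    probability P[|U - mu| >= |U_obs - mu|] over all C(n, n1) group splits of
    the observed pooled values (valid under ties).  Larger samples use the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2.0
    ranks = sps.rankdata(pooled)  # average ranks under ties
    u_obs = _rank_u(ranks, tuple(range(n1)), n1)
    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(mu, 1.0, "degenerate", True)
    if n1 + n2 <= exact_max_n:
        dev_obs = abs(u_obs - mu) - 1e-9
        total = comb(n1 + n2, n1)
        hits = sum(
            abs(_rank_u(ranks, idx, n1) - mu) >= dev_obs
            for idx in combinations(range(n1 + n2), n1)
        )
        return MannWhitneyResult(u_obs, hits / total, "exact-permutation", False)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                             "normal-approximation", False)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks under ties; NaNs dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), int(x.size), True)
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(float(rho), float(p), int(x.size), False)
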