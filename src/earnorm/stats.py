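"""Comparison statistics: Pearson r, exact Mann-Whitney U, box summaries.

The Mann-Whitney two-tailed U-test is the workhorse for skewed expression
data (e.g. comparing a transcript's normalized level between patients and
controls).  For small tie-free samples the exact null distribution of U is
obtained by enumerating every assignment of ranks to the first group —
C(n1+n2, n1) equally likely arrangements — and the two-sided p-value is the
null probability of a U at least as far from its mean n1*n2/2 as the one
observed.  Larger or tied samples fall back to the normal approximation
with tie and continuity corrections.

Box summaries follow the percentile convention common in expression plots:
box edges at the 25th/75th percentiles, the median line, and 10th/90th
percentile whiskers drawn only when ten or more samples are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import DomainError, InsufficientDataError

#: exact enumeration is used up to this combined sample size (tie-free data)
EXACT_ENUMERATION_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int


@dataclass(frozen=True)
class BoxSummary:
    """Percentile box: quartiles always, 10/90 whiskers only when n >= 10."""

    n: int
    p25: float
    median: float
    p75: float
    p10: Optional[float] = None
    p90: Optional[float] = None


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("series lengths differ")
    if x.size < 3:
        raise InsufficientDataError("Pearson correlation needs >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a zero-variance series")
    res = sp_stats.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="pearson", n1=int(x.size), n2=int(y.size))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: number of (a_i, b_j) pairs with a_i > b_j (+0.5 per tie)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U-test, exact for small tie-free samples.

    The exact path enumerates all C(n1+n2, n1) rank assignments and returns
    p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) under the null; it runs when
    n1 + n2 <= 16 and the pooled data are tie-free.  Otherwise the normal
    approximation with tie correction and continuity correction is used.
    The ``method`` field records which path ran.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    n1, n2 = int(a.size), int(b.size)
    u_obs = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        # ranks 1..N of the pooled sample; U of group a from its rank sum
        order = np.argsort(pooled)
        ranks = np.empty(pooled.size)
        ranks[order] = np.arange(1, pooled.size + 1)
        mean_u = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mean_u)
        total = comb(n1 + n2, n1)
        hits = 0
        all_ranks = np.arange(1, n1 + n2 + 1)
        for subset in combinations(range(n1 + n2), n1):
            u = all_ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mean_u) >= dev_obs - 1e-12:
                hits += 1
        return TestResult(statistic=u_obs, p_value=hits / total,
                          method="exact_enumeration", n1=n1, n2=n2)

    res = sp_stats.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
    return TestResult(statistic=u_obs, p_value=float(res.pvalue),
                      method="normal_approximation", n1=n1, n2=n2)


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Percentile summary (linear interpolation between order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise InsufficientDataError("box summary needs >= 1 value")
    p25, med, p75 = np.percentile(values, [25, 50, 75])
    if values.size >= 10:
        p10, p90 = np.percentile(values, [10, 90])
        return BoxSummary(n=int(values.size), p25=float(p25), median=float(med),
                          p75=float(p75), p10=float(p10), p90=float(p90))
    return BoxSummary(n=int(values.size), p25=float(p25), median=float(med),
                      p75=float(p75))
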