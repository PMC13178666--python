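"""Cohort-level statistics: t-tests, exact contingency tests, proportions.

These are the tests applied to the per-cell and per-patient measurement
tables produced by the imaging stages: a two-tailed Welch t-test for
continuous comparisons (per-cell CBF, cilia length, ciliation level),
Fisher's exact test for beat-mode contingency tables, and rounded
percentage summaries for cohort fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sstats

__all__ = [
    "TTestResult",
    "ProportionSummary",
    "welch_t_test",
    "fisher_exact",
    "fisher_exact_mc",
    "proportion_summary",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass
class ProportionSummary:
    numerator: int
    denominator: int
    percent: int  # round-half-up integer percent

    def __str__(self) -> str:
        return f"{self.numerator} of {self.denominator} ({self.percent}%)"


def welch_t_test(a, b, equal_var: bool = False) -> TTestResult:
    """Two-tailed t-test of two groups (Welch by default).

    Zero variance in both groups is degenerate: equal means give
    (t=0, p=1); different means give p -> 0 with the degenerate flag set.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, float(a.size + b.size - 2), 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, a.mean() - b.mean()),
                           float(a.size + b.size - 2), 0.0, degenerate=True)
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def _fisher_2xk(table: np.ndarray) -> float:
    """Two-sided exact p for a 2xK table: sum of P(T) <= P(observed).

    Enumerates all tables with the observed margins; the probability of
    a table with top row (a_1..a_K), column totals (c_1..c_K) and row
    total r is  prod_j C(c_j, a_j) / C(N, r).
    """
    col = table.sum(axis=0)
    r = int(table[0].sum())
    n = int(table.sum())
    logdenom = math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    def logprob(tops) -> float:
        s = 0.0
        for a, c in zip(tops, col):
            if a < 0 or a > c:
                return -math.inf
            s += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
        return s - logdenom

    obs = logprob(table[0])
    eps = 1e-9
    total = 0.0
    ranges = [range(int(c) + 1) for c in col[:-1]]
    for tops in product(*ranges):
        last = r - sum(tops)
        if last < 0 or last > col[-1]:
            continue
        lp = logprob(list(tops) + [last])
        if lp <= obs + eps:
            total += math.exp(lp)
    return min(total, 1.0)


def fisher_exact(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 (or small 2xK) contingency table.

    Two-sided p is the sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's.  Returns (p, odds_ratio); the odds ratio is NaN for
    K > 2.  ``alternative="doubled"`` instead doubles the smaller tail
    (2x2 only), a convention some software uses.

    2xK tables are enumerated exactly only for K <= 4 and total <= 40;
    larger tables raise and point to :func:`fisher_exact_mc`.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("table must be 2 x K")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("empty table: no observations")
    k = table.shape[1]
    if k == 2:
        a, b = table[0]
        c, d = table[1]
        odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
        if alternative == "doubled":
            p_less = float(sstats.hypergeom.cdf(a, table.sum(), a + b, a + c))
            p_greater = float(sstats.hypergeom.sf(a - 1, table.sum(), a + b, a + c))
            return min(1.0, 2.0 * min(p_less, p_greater)), odds
        return _fisher_2xk(table), odds
    if alternative != "two-sided":
        raise ValueError("only the two-sided sum-of-small-p test is defined for 2xK")
    if k > 4 or table.sum() > 40:
        raise ValueError(
            "exact enumeration is limited to K <= 4 and total <= 40; "
            "use fisher_exact_mc for larger tables"
        )
    return _fisher_2xk(table), float("nan")


def fisher_exact_mc(table, n_resamples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo two-sided Fisher p for 2xK tables too large to enumerate.

    Samples tables with the observed margins (multivariate
    hypergeometric) and reports the fraction at most as probable as the
    observed one (with the +1 correction keeping p > 0).
    """
    table = np.asarray(table, dtype=np.int64)
    col = table.sum(axis=0)
    r = int(table[0].sum())
    n = int(table.sum())
    rng = np.random.default_rng(seed)
    logdenom = math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    def logprob(tops) -> float:
        s = 0.0
        for a, c in zip(tops, col):
            s += math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
        return s - logdenom

    obs = logprob(table[0])
    draws = rng.multivariate_hypergeometric(col, r, size=n_resamples)
    lps = np.array([logprob(t) for t in draws])
    hits = int(np.sum(lps <= obs + 1e-9))
    return (hits + 1) / (n_resamples + 1)


def proportion_summary(k: int, n: int) -> ProportionSummary:
    """Cohort fraction as a round-half-up integer percentage.

    proportion_summary(19, 31) prints "19 of 31 (61%)"; rounding is half
    up in exact integer arithmetic (18.75% -> 19%).
    """
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= k <= n):
        raise ValueError("numerator must lie in [0, denominator]")
    percent = (200 * k + n) // (2 * n)
    return ProportionSummary(k, n, int(percent))
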