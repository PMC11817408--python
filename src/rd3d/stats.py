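"""Statistical kernels shared by every analysis stage.

Two primitives are used everywhere: the two-sided Fisher exact test on a
2x2 table and Benjamini-Hochberg adjustment within one test family.
The Fisher two-sided p-value uses the probability-mass rule: it sums the
hypergeometric probabilities of all tables with the same margins whose
probability does not exceed the observed table's, with a small relative
tolerance for floating-point ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: relative tolerance when deciding which tables tie with the observed one
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """A 2x2 test outcome: counts, odds ratio (NaN when undefined), p and q."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def _family_pvalues(r1: int, r2: int, c1: int) -> np.ndarray:
    """Two-sided Fisher p for every table with row margins (r1, r2), first
    column margin c1.

    Returns p indexed by a - a_min where a (top-left cell) ranges over the
    hypergeometric support [max(0, c1 - r2), min(r1, c1)].
    """
    n = r1 + r2
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = np.arange(a_min, a_max + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    # p[i] = sum of pmf over tables at most as probable as table i
    thresh = pmf[:, None] * (1.0 + TIE_RTOL)
    p = np.where(pmf[None, :] <= thresh, pmf[None, :], 0.0).sum(axis=1)
    return np.minimum(p, 1.0)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    Parameters
    ----------
    table
        2x2 array-like of non-negative integer counts [[a, b], [c, d]].

    Returns
    -------
    (odds_ratio, p_value)
        ``odds_ratio = a*d / (b*c)``, NaN when ``b*c == 0`` (undefined);
        degenerate margins give p = 1.
    """
    (a, b), (c, d) = ((int(x), int(y)) for x, y in table)
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == r1 + r2:
        return odds, 1.0
    p = _family_pvalues(r1, r2, c1)[a - max(0, c1 - r2)]
    return odds, float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted family, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def chi2_1df(observed: float, total: float, expected_fraction: float) -> tuple[float, float]:
    """One-degree-of-freedom chi-square of in-state vs out-of-state counts.

    Compares [observed, total - observed] against
    [e * total, (1 - e) * total] for expected fraction e in (0, 1).
    Returns (statistic, p).
    """
    e = expected_fraction
    if not (0.0 < e < 1.0) or total <= 0:
        return float("nan"), float("nan")
    exp_in = e * total
    exp_out = (1.0 - e) * total
    stat = (observed - exp_in) ** 2 / exp_in + ((total - observed) - exp_out) ** 2 / exp_out
    return float(stat), float(sps.chi2.sf(stat, df=1))


def mannwhitney_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples without ties, the
    tie-corrected normal approximation otherwise. Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.array_equal(np.sort(x), np.sort(y)):
        # identical samples carry no evidence either way
        return float(x.size * y.size / 2.0), 1.0
    pooled = np.concatenate([x, y])
    method = "exact" if (x.size + y.size <= 25 and np.unique(pooled).size == pooled.size) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def poisson_upper_tail(observed, expected) -> np.ndarray:
    """P(X >= observed) for X ~ Poisson(expected), vectorised."""
    observed = np.asarray(observed, dtype=np.int64)
    expected = np.asarray(expected, dtype=float)
    return sps.poisson.sf(observed - 1, expected)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its p-value."""
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def format_pvalue(p: float) -> str:
    """Scientific-notation p/q formatting; underflow reported as < 1e-300."""
    if p != p:  # NaN
        return "nan"
    if 0 < p < 1e-300:
        return "< 1e-300"
    return f"{p:.6e}"


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> float:
    """Cross-product odds ratio, NaN when the denominator is zero."""
    return (a * d) / (b * c) if b * c > 0 else float("nan")


def exact_fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p via exact integer enumeration.

    Independent of :func:`fisher_exact_2x2`: hypergeometric weights are
    integer binomial products, the tie rule uses exact comparison scaled
    by the same relative tolerance. Intended for tests.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(a_min, a_max + 1)]
    w_obs = weights[a - a_min]
    total = math.comb(n, c1)
    tail = sum(w for w in weights if w <= w_obs * (1.0 + TIE_RTOL))
    return min(tail / total, 1.0)
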