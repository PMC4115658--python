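"""Shared exact-test and multiple-testing primitives.

All two-sided Fisher p-values in this package go through
:func:`fisher_two_sided`, which uses the probability-summation rule: the
p-value is the total null probability of all tables (with the observed
margins) whose point probability does not exceed that of the observed
table.  A small relative slack absorbs floating-point noise when ranking
point probabilities, so exact ties (symmetric tables) are always included.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st
from scipy.special import gammaln as _gammaln

# Relative slack when comparing point probabilities computed in floating
# point; two mathematically equal pmf values may differ by ~1e-16.
_PMF_SLACK = 1e-7

__all__ = [
    "fisher_support_pvalues",
    "fisher_two_sided",
    "bh_adjust",
    "binom_upper_pvalue",
    "binom_one_sided",
]


def _log_comb(n, k):
    return _gammaln(n + 1) - _gammaln(k + 1) - _gammaln(n - k + 1)


def fisher_support_pvalues(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p-values for every table with margins (r1, r2, c1).

    Returns ``(support, pvals)`` where ``support`` lists the possible values
    of the top-left cell ``a`` and ``pvals[i]`` is the two-sided p-value of
    the table ``[[a, r1-a], [c1-a, r2-c1+a]]``.
    """
    n = r1 + r2
    if c1 < 0 or c1 > n:
        raise ValueError("column margin outside table total")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf via log-gamma (much cheaper than the frozen
    # scipy.stats.hypergeom machinery when called per window/gene)
    logpmf = (
        _log_comb(r1, support)
        + _log_comb(r2, c1 - support)
        - _log_comb(n, c1)
    )
    pmf = np.exp(logpmf)
    # For each observed a, sum pmf over tables at most as probable.
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    # index of the last sorted pmf <= pmf[a] * (1 + slack)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + _PMF_SLACK), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return support, pvals


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table (probability summation)."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("negative cell count")
    if a + b + c + d == 0:
        return 1.0
    support, pvals = fisher_support_pvalues(a + b, c + d, a + c)
    return float(pvals[int(a) - int(support[0])])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j``, clipped to [0, 1]; NaNs are
    passed through and do not count toward ``m``.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[mask] = out
    return q


def binom_upper_pvalue(k: int, n: int, p0: float) -> float:
    """P(X >= k | n, p0) for X ~ Binomial(n, p0); equals 1 when n == 0."""
    if k < 0 or k > n:
        raise ValueError("k outside [0, n]")
    if n == 0:
        return 1.0
    return float(_st.binom.sf(k - 1, n, p0))


def binom_one_sided(k: int, n: int, p0: float, direction: str) -> float:
    """One-sided exact binomial p-value (direction 'less' or 'greater')."""
    if n < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("successes outside [0, total]")
    if direction == "greater":
        return float(_st.binom.sf(k - 1, n, p0))
    if direction == "less":
        return float(_st.binom.cdf(k, n, p0))
    raise ValueError(f"unknown direction {direction!r}")
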