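"""Shared statistical primitives: BH step-up FDR, the hypergeometric upper
tail used by the shared-miRNA and GO tests, and vectorised Pearson screening.
"""

from __future__ import annotations

from math import lgamma

import numpy as np
from scipy import stats as sps


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i}( p_(j) * m / j ) over p sorted ascending, mapped
    back to the input order; ties broken by a stable sort on (p, index).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -np.inf
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def hypergeom_upper_tail(N: int, M: int, L: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, L, M), evaluated in log space.

    The urn holds N balls of which L are marked; M are drawn without
    replacement; X counts drawn marked balls.  Equivalently this is
    1 - sum_{i=0}^{k-1} C(L,i) C(N-L, M-i) / C(N,M), the over-representation
    p-value for an overlap of k between a set of size M and a set of size L
    in a universe of size N.
    """
    if N < 0 or M < 0 or L < 0:
        raise ValueError("N, M, L must be non-negative")
    if M > N or L > N:
        raise ValueError("M and L must not exceed N")
    if k < 0 or k > min(M, L):
        raise ValueError("k must lie in [0, min(M, L)]")
    if k == 0:
        return 1.0
    denom = _log_comb(N, M)
    terms = []
    for i in range(k, min(M, L) + 1):
        t = _log_comb(L, i) + _log_comb(N - L, M - i) - denom
        if np.isfinite(t):
            terms.append(t)
    if not terms:
        return 0.0
    mx = max(terms)
    total = mx + np.log(np.sum(np.exp(np.asarray(terms) - mx)))
    return float(min(1.0, np.exp(total)))


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of ``a`` and every row of ``b``.

    Rows are observations over the same ordered samples.  Zero-variance rows
    yield NaN correlations (callers skip and count them).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("row length mismatch")
    az = a - a.mean(axis=1, keepdims=True)
    bz = b - b.mean(axis=1, keepdims=True)
    asd = np.sqrt((az**2).sum(axis=1))
    bsd = np.sqrt((bz**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (az @ bz.T) / np.outer(asd, bsd)
    return np.clip(r, -1.0, 1.0, out=r)


def pearson_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r under the t distribution with n-2 df."""
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
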