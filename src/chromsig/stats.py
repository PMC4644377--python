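"""Exact and classical statistics shared across the pipeline.

Small, dependency-light routines used by several stages: Fisher's exact
test on 2x2 tables (read-depth and peak-count comparisons), one-sided
binomial tails (per-chromosome enrichment), Benjamini-Hochberg FDR
control (differential binding), the paired t-test (normalized signal
comparisons between tissue groups) and Spearman rank correlation.

``fisher_exact_2x2`` and ``binomial_upper_tail`` are implemented by
direct enumeration/summation so that they can be checked term-by-term
against independent oracles; ``paired_t_test`` and
``spearman_correlation`` delegate the distributional work to scipy.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

__all__ = [
    "fisher_exact_2x2",
    "binomial_upper_tail",
    "binomial_lower_tail",
    "bh_fdr",
    "paired_t_test",
    "spearman_correlation",
    "PairedTResult",
    "SpearmanResult",
]

#: relative tolerance when comparing table probabilities in the
#: two-sided Fisher rule ("sum of tables at most as probable").
_FISHER_REL_TOL = 1e-12


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    The two margins are held fixed and every table consistent with them
    is enumerated under the hypergeometric null; the two-sided p-value
    is the total probability of tables whose probability does not
    exceed that of the observed table (up to a 1e-12 relative
    tolerance guarding float equality).

    Parameters
    ----------
    table : 2x2 array-like of int
        Rows are groups, columns are outcome classes.

    Returns
    -------
    float
        Two-sided p-value.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table cells must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table")

    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (c + d))
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    # log P(k) under the hypergeometric with margins (r1, r2 | c1, c2)
    logp = (
        _log_comb(r1, ks)
        + _log_comb(c + d, c1 - ks)
        - _log_comb(total, c1)
    )
    p_obs = logp[ks == a][0]
    keep = logp <= p_obs + math.log1p(_FISHER_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial p-value P(X >= k), X ~ Binomial(n, p0).

    Summed term-by-term in log space for numerical stability; exact for
    any k, n within float range.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    if k == 0:
        return 1.0
    i = np.arange(k, n + 1)
    logterms = _log_comb(n, i) + i * math.log(p0) + (n - i) * math.log1p(-p0)
    return float(min(1.0, np.exp(logsumexp(logterms))))


def binomial_lower_tail(k: int, n: int, p0: float) -> float:
    """Lower-tail binomial p-value P(X <= k), log-stable summation."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"require 0 < p0 < 1, got {p0}")
    if k == n:
        return 1.0
    i = np.arange(0, k + 1)
    logterms = _log_comb(n, i) + i * math.log(p0) + (n - i) * math.log1p(-p0)
    return float(min(1.0, np.exp(logsumexp(logterms))))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of min(1, p_(j) * m / j) on the sorted
    p-vector, mapped back to the input order. Monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float


def paired_t_test(x, y) -> PairedTResult:
    """Paired two-sided t-test on matched vectors.

    All-zero differences return t = 0, p = 1 by convention (scipy would
    return NaN); a zero-variance nonzero difference gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, df, 1.0)
        return PairedTResult(math.copysign(math.inf, mean), df, 0.0)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(float(t), df, float(p))


class SpearmanResult(NamedTuple):
    rho: float
    p: float


def spearman_correlation(x, y, *, exact: bool = False) -> SpearmanResult:
    """Spearman rank correlation with t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged). With
    ``exact=True`` (n <= 10) the p-value is computed by exhaustive
    permutation of one vector instead of the t-approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if exact:
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return SpearmanResult(rho, count / total)
    # t-approximation, guarded against |rho| = 1
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, float(p))
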