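"""Core statistical tests: hypergeometric upper tail and Mann-Whitney.

Both tests are implemented here rather than delegated so their exact
behaviour (log-space tail accumulation; the exact-enumeration branch and
its cutoff) is pinned down by this package's contract; the test suite
cross-checks them against scipy.stats as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

__all__ = ["TestResult", "hypergeom_sf", "mann_whitney"]

EXACT_CUTOFF = 8  # largest min(n1, n2) for the exact Mann-Whitney branch


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # hypergeometric | mw_exact | mw_normal
    n1: int
    n2: int


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def hypergeom_sf(a: int, K: int, n: int, N: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N, K, n).

    The population has N items of which K are successes; n items are drawn
    without replacement; X counts drawn successes. Terms are accumulated in
    log space so the tail stays finite for N ~ 1e6.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    lo = max(0, n + K - N)
    hi = min(K, n)
    if a < lo or a > hi + 1:
        if a <= lo:
            return 1.0
        raise ValueError(f"a={a} outside support [{lo}, {hi}]")
    if a <= lo:
        return 1.0
    if a > hi:
        return 0.0
    k = np.arange(a, hi + 1)
    log_terms = _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _exact_u_cdf_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U as counts over 0..n1*n2 (no ties).

    Classic recurrence over the number of rank arrangements: f(n1, n2, u)
    built by adding one observation at a time.
    """
    max_u = n1 * n2
    # dp[u] = number of arrangements of the n1 group giving U = u
    dp = np.zeros(max_u + 1, dtype=float)
    dp[0] = 1.0
    # iterative version of f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u)
    table = {(0, 0): dp}
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if (i, j) in table:
                continue
            cur = np.zeros(max_u + 1)
            if i > 0:
                prev = table[(i - 1, j)]
                if j:
                    cur[j:] += prev[: max_u + 1 - j]
                else:
                    cur += prev
            if j > 0:
                cur += table[(i, j - 1)]
            table[(i, j)] = cur
    return table[(n1, n2)]


def mann_whitney(x, y, alternative: str = "two-sided",
                 exact_cutoff: int = EXACT_CUTOFF,
                 continuity: bool = True) -> TestResult:
    """Mann-Whitney/Wilcoxon rank-sum test with midranks for ties.

    Uses exact enumeration of the null U distribution when
    ``min(n1, n2) <= exact_cutoff`` and the pooled data are tie-free;
    otherwise the normal approximation with tie-corrected variance and an
    optional continuity correction. Two-sided p doubles the smaller tail
    and is capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if min(n1, n2) <= exact_cutoff and not has_ties:
        counts = _exact_u_cdf_counts(n1, n2)
        total = counts.sum()
        cdf = np.cumsum(counts) / total  # P(U <= u)
        u1_int = int(round(u1))
        p_le = cdf[u1_int]                       # P(U1 <= u1)
        p_ge = 1.0 - (cdf[u1_int - 1] if u1_int > 0 else 0.0)  # P(U1 >= u1)
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_le, p_ge))
        elif alternative == "greater":
            p = p_ge
        else:
            p = p_le
        return TestResult(float(u1), float(p), "mw_exact", n1, n2)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        # all pooled values identical: no evidence of any location shift
        return TestResult(float(u1), 1.0, "mw_normal", n1, n2)
    sd = np.sqrt(var_u)
    from scipy.stats import norm

    def tail(u: float, upper: bool) -> float:
        delta = u - mean_u
        cc = 0.5 if continuity else 0.0
        if upper:
            z = (delta - cc) / sd
            return float(norm.sf(z))
        z = (delta + cc) / sd
        return float(norm.cdf(z))

    p_ge = tail(u1, upper=True)
    p_le = tail(u1, upper=False)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_le, p_ge))
    elif alternative == "greater":
        p = p_ge
    else:
        p = p_le
    return TestResult(float(u1), float(p), "mw_normal", n1, n2)
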