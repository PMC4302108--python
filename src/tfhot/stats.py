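"""Shared statistical helpers: Mann-Whitney U, hypergeometric tails,
two-proportion z-test.

Conventions: all tests are two-sided unless stated; p-values are reported
raw (a Benjamini-Hochberg column is offered downstream but never gates
results).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Uses exact enumeration when ``min(n, m) <= 8`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= 8 and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hypergeom_tails(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Upper (enrichment) and lower (depletion) hypergeometric tails.

    ``k`` successes in a draw of ``n`` from a universe of ``N`` containing
    ``K`` successes. Upper tail is P(X >= k); lower tail P(X <= k). The two
    tails share the point mass at k, so they sum to >= 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(f"overlap k={k} impossible for n={n}, K={K}, N={N}")
    upper = float(sps.hypergeom.sf(k - 1, N, K, n))
    lower = float(sps.hypergeom.cdf(k, N, K, n))
    return min(upper, 1.0), min(lower, 1.0)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided pooled two-proportion z-test; returns (z, p).

    Degenerate pooled proportions (0 or 1, i.e. no variance) give z = 0,
    p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
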