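"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and where possible the
libraries) they verify: ranks by exhaustive counting, correlation via
exact rational covariance, regression via an explicit normal-equations /
sum-of-squares decomposition.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def brute_ranks(x) -> list[Fraction]:
    """Average ranks by counting: 1 + #smaller + (#equal - 1)/2."""
    x = list(x)
    return [
        Fraction(1) + sum(1 for w in x if w < v)
        + Fraction(sum(1 for w in x if w == v) - 1, 2)
        for v in x
    ]


def brute_spearman(x, y) -> float:
    """Definition-based rho: exact rational covariance of ranks, then one
    float division — independent of the vectorized implementation."""
    rx, ry = brute_ranks(x), brute_ranks(y)
    n = len(rx)
    mx = sum(rx, Fraction(0)) / n
    my = sum(ry, Fraction(0)) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return float(cov) / math.sqrt(float(vx * vy))


def brute_hierarchical(y, b1, b2):
    """R²-change by explicit sum-of-squares decomposition.

    Solves both nested models through the normal equations and forms the
    F statistic from residual sums of squares directly:
    F = ((SSE1 - SSE2)/q) / (SSE2 / (n - p_full - 1)).
    """
    y = np.asarray(y, float)
    b1 = np.atleast_2d(np.asarray(b1, float).T).T
    b2 = np.atleast_2d(np.asarray(b2, float).T).T
    n = y.size
    one = np.ones((n, 1))
    X1 = np.hstack([one, b1])
    X2 = np.hstack([one, b1, b2])

    def sse(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    sst = float(((y - y.mean()) ** 2).sum())
    sse1, sse2 = sse(X1), sse(X2)
    r2_1 = 1 - sse1 / sst
    r2_2 = 1 - sse2 / sst
    q = b2.shape[1]
    df2 = n - (b1.shape[1] + q) - 1
    f = ((sse1 - sse2) / q) / (sse2 / df2)
    return r2_1, r2_2, r2_2 - r2_1, f
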