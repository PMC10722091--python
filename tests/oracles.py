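"""Independent brute-force oracles used to validate the implementation.

Each function here is deliberately written from first principles (loops,
enumeration, closed forms) and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def midranks(values) -> list[float]:
    """Mid-ranks computed by counting, not by library rankdata."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        # average of ranks less+1 .. less+equal
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def spearman_bruteforce(x, y) -> float:
    """Spearman rho as the Pearson correlation of hand-computed mid-ranks."""
    rx = midranks(x)
    ry = midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by explicit enumeration."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def bh_stepup(p) -> list[float]:
    """Benjamini–Hochberg adjusted p-values by the textbook step-up rule."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def cv_percent(values) -> float:
    """Coefficient of variation (%) with the n−1 standard deviation."""
    vals = list(values)
    n = len(vals)
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return 100.0 * sd / mean


def nw_affine_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score with affine gaps (Gotoh DP).

    ``sub[(x, y)]`` is the substitution score; a gap of length L costs
    ``gap_open + (L-1)*gap_extend`` (both positive penalties).
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to gap)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[(a[i - 1], b[j - 1])]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def identity_from_alignment(aligned_a: str, aligned_b: str) -> float:
    """Percent identity over the full alignment length, gaps included."""
    assert len(aligned_a) == len(aligned_b)
    ident = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-" and y != "-"
    )
    return 100.0 * ident / len(aligned_a)
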