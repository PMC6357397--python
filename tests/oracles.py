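"""Independent textbook-formula oracles used only by the test suite.

Deliberately written with plain loops and explicit formulas, sharing no
code with the package: these are the brute-force references that the
vectorized implementation is checked against.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import scipy.stats as sps


def pearson_oracle(x, y):
    """Product-moment correlation with the two-sided t test, by loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


def _ranks(v):
    """Average ranks (1-based), computed by explicit sorting."""
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho = Pearson on average-tie ranks; t approximation."""
    return pearson_oracle(_ranks(list(x)), _ranks(list(y)))


@lru_cache(maxsize=None)
def _inversion_counts(n: int) -> tuple:
    """Number of permutations of n items with k inversions (Mahonian)."""
    counts = [1]
    for i in range(2, n + 1):
        new = [0] * (len(counts) + i - 1)
        for k, c in enumerate(counts):
            for d in range(i):
                new[k + d] += c
        counts = new
    return tuple(counts)


def kendall_oracle(x, y):
    """Kendall tau-b with exact p (tie-free, n<=33) or the tie-corrected
    normal approximation."""
    n = len(x)
    S = 0
    for i in range(n):
        for j in range(i + 1, n):
            S += int(np.sign((x[i] - x[j]) * (y[i] - y[j])))

    def tie_sizes(v):
        from collections import Counter
        return [c for c in Counter(v).values() if c > 1]

    tx, ty = tie_sizes(list(x)), tie_sizes(list(y))
    n0 = n * (n - 1) // 2
    n1 = sum(t * (t - 1) // 2 for t in tx)
    n2 = sum(t * (t - 1) // 2 for t in ty)
    tau = S / math.sqrt((n0 - n1) * (n0 - n2))
    tau = max(-1.0, min(1.0, tau))

    if not tx and not ty and n <= 33:
        dis = (n0 - S) // 2
        counts = _inversion_counts(n)
        c = min(dis, n0 - dis)
        p = 2 * sum(counts[: c + 1]) / math.factorial(n)
        return tau, min(1.0, p)

    x1 = sum(t * (t - 1) * (2 * t + 5) for t in tx)
    y1 = sum(t * (t - 1) * (2 * t + 5) for t in ty)
    x0 = sum(t * (t - 1) * (t - 2) for t in tx)
    y0 = sum(t * (t - 1) * (t - 2) for t in ty)
    xtie = sum(t * (t - 1) // 2 for t in tx)
    ytie = sum(t * (t - 1) // 2 for t in ty)
    var = ((n * (n - 1) * (2 * n + 5) - x1 - y1) / 18
           + (2 * xtie * ytie) / (n * (n - 1))
           + x0 * y0 / (9 * n * (n - 1) * (n - 2)))
    z = S / math.sqrt(var)
    return tau, 2 * sps.norm.sf(abs(z))


ORACLES = {"pearson": pearson_oracle, "spearman": spearman_oracle,
           "kendall": kendall_oracle}


def bh_oracle(pvals):
    """Benjamini–Hochberg step-up, applied literally from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
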