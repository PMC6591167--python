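"""Independent, loop-based reimplementations of the printed statistics.

These serve as oracles: they are written directly from the defining
formulas (K-1 denominators, explicit sums over index sets) and share no
code with the package's vectorized implementations.
"""

import math
from itertools import combinations

import numpy as np


def naive_mean(x):
    return sum(x) / len(x)


def naive_sd(x):
    m = naive_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def naive_corr(x, y):
    mx, my = naive_mean(x), naive_mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return num / ((len(x) - 1) * naive_sd(x) * naive_sd(y))


def naive_v1(X, Y):
    """s_i(X)/s_i(Y) per gene; X, Y are genes x samples arrays."""
    return np.array([naive_sd(X[i]) / naive_sd(Y[i]) for i in range(X.shape[0])])


def naive_v2(X, Y, s1):
    """sum over j in S1 of |r_ij(X)| - |r_ij(Y)|, for i in S1 (self-term included)."""
    out = {}
    for i in s1:
        out[i] = sum(
            abs(naive_corr(X[i], X[j])) - abs(naive_corr(Y[i], Y[j])) for j in s1
        )
    return out


def naive_v3(X, Y, s0, s1):
    """sum over j in S0 \\ S1 of |r_ij(X)| - |r_ij(Y)|, for i in S1."""
    outside = [j for j in s0 if j not in set(s1)]
    out = {}
    for i in s1:
        out[i] = sum(
            abs(naive_corr(X[i], X[j])) - abs(naive_corr(Y[i], Y[j])) for j in outside
        )
    return out


def naive_is(Z, genes):
    return naive_mean([naive_sd(Z[i]) for i in genes])


def naive_ir(Z, genes, c):
    pairs = list(combinations(genes, 2))
    return naive_mean([abs(naive_corr(Z[i], Z[j])) for i, j in pairs]) - c


def naive_bh_reject(pvals, q):
    """Brute-force step-up: evaluate all m thresholds, reject ranks <= best k."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    best_k = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            best_k = k
    rejected = [False] * m
    for rank in range(best_k):
        rejected[order[rank]] = True
    return np.array(rejected)


def naive_hypergeom_upper(N, n1, n2, x):
    """P(overlap >= x) by exhaustive enumeration over all C(N, n2) draws."""
    universe = range(N)
    target = set(range(n1))
    hits = total = 0
    for draw in combinations(universe, n2):
        total += 1
        if len(target & set(draw)) >= x:
            hits += 1
    return hits / total


def naive_trimmed_mean(values, trim_frac):
    n = len(values)
    k = math.floor(trim_frac * n)
    ordered = sorted(values)
    kept = ordered[k : n - k] if k else ordered
    return sum(kept) / len(kept)
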