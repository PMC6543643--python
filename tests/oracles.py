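"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately written from first principles (plain
loops, full enumeration) and never calls the implementation under test.
"""

from itertools import combinations

import numpy as np


def enumerate_u_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Valid for tie-free samples; returns (U_observed, p).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    mu = n1 * len(y) / 2
    idx = range(len(pooled))
    count = total = 0
    for chosen in combinations(idx, n1):
        xs = pooled[list(chosen)]
        ys = pooled[[i for i in idx if i not in chosen]]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total


def gotoh_score(a, b, match=1.0, mismatch=0.0, open_=-5.0, extend=-1.0):
    """Affine-gap global alignment score by plain dynamic programming."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)  # gap in b (consumes a)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Iy[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + extend)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + extend)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def screening_predicate(row):
    """Row-by-row restatement of the retention cascade."""
    elevated = {"aioA", "arrA", "arxA"}
    return (
        row.score > 100
        and row.percent_alignment > 90
        and (row.gene not in elevated or row.score > 1000)
    )
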