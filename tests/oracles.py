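"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations that share no code with the package:
manual average-rank transform + np.corrcoef for Spearman, pairwise-count U
statistic enumeration for the exact rank-sum test, and a literal step-up
loop for BH.
"""

from itertools import combinations
from math import comb

import numpy as np


def manual_ranks(v):
    """Average ranks computed by explicit tie-group walking."""
    v = np.asarray(v, dtype=float)
    order = np.argsort(v, kind="stable")
    sv = v[order]
    ranks = np.empty(len(v), dtype=float)
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y):
    """Rank transform then Pearson via np.corrcoef."""
    return float(np.corrcoef(manual_ranks(x), manual_ranks(y))[0, 1])


def oracle_exact_ranksum_p(group1, group2):
    """Two-sided exact p via the Mann-Whitney U statistic (pairwise counts)."""
    pooled = list(group1) + list(group2)
    n1, n = len(group1), len(pooled)

    def u_stat(idx):
        sel = set(idx)
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(n) if i not in sel]
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    mu = n1 * (n - n1) / 2.0
    dev_obs = abs(u_stat(range(n1)) - mu)
    count = sum(
        1
        for idx in combinations(range(n), n1)
        if abs(u_stat(idx) - mu) >= dev_obs - 1e-12
    )
    return count / comb(n, n1)


def oracle_bh(pvals):
    """Literal BH step-up: q_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(1.0, m * p[order[j - 1]] / j) for j in range(pos, m + 1)
        )
    return q
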