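"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a statistic from first principles without touching
the package's implementation (and without the scipy/statsmodels routines
the package delegates to), so implementation-vs-oracle comparisons are a
genuine dual route.
"""

from itertools import combinations
from math import comb, erf, sqrt

import numpy as np


def average_ranks(x):
    """Ascending ranks with ties averaged, by explicit sorting."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def interp_quantile(x, q):
    """Linear-interpolation quantile at index h = (n-1)q + 1."""
    s = np.sort(np.asarray(x, dtype=float))
    h = (len(s) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def outlier_score_brute(values, is_tumor, q_low, q_high, delta):
    """Rank-sum outlier score, both tails, by direct enumeration."""
    values = np.asarray(values, dtype=float)
    is_tumor = np.asarray(is_tumor, dtype=bool)
    normals = values[~is_tumor]
    n = len(values)
    lo = interp_quantile(normals, q_low)
    hi = interp_quantile(normals, q_high)
    ranks = average_ranks(values)
    s_right = sum(ranks[i] for i in range(n)
                  if is_tumor[i] and values[i] > hi and values[i] - hi >= delta) / n
    s_left = sum(n + 1 - ranks[i] for i in range(n)
                 if is_tumor[i] and values[i] < lo and lo - values[i] >= delta) / n
    return s_right, s_left


def spearman_brute(x, y):
    """Rank both vectors (average ties), then Pearson via the definition."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def pooled_t_brute(a, b):
    """Closed-form pooled two-sample t and its two-sided p (via the
    incomplete-beta representation of the t CDF)."""
    from scipy.special import betainc  # special function only, not a test

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    t = (a.mean() - b.mean()) / sqrt(sp2 * (1 / n1 + 1 / n2))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return float(t), float(p)


def hypergeom_prob(a, b, c, d):
    """P(table | margins) = C(a+b,a) C(c+d,c) / C(n, a+c)."""
    return comb(a + b, a) * comb(c + d, c) / comb(a + b + c + d, a + c)


def fisher_two_sided_brute(a, b, c, d):
    """Two-sided Fisher exact by enumerating all tables with the observed
    margins and summing those no more probable than the observed."""
    r1, r2, c1 = a + b, c + d, a + c
    p_obs = hypergeom_prob(a, b, c, d)
    total = 0.0
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = hypergeom_prob(a2, r1 - a2, c1 - a2, r2 - (c1 - a2))
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def bh_stepup_brute(p):
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running_min = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        running_min = min(running_min, p[i] * n / (rank_pos + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def rank_sum_exact_brute(ranks, set_idx, alternative):
    """Exact tail probability of the set's rank sum over all assignments."""
    ranks = np.asarray(ranks, dtype=float)
    k = len(set_idx)
    w = ranks[list(set_idx)].sum()
    eps = 1e-9
    n_extreme = 0
    total = 0
    for idx in combinations(range(len(ranks)), k):
        s = ranks[list(idx)].sum()
        total += 1
        if alternative == "up" and s >= w - eps:
            n_extreme += 1
        elif alternative == "down" and s <= w + eps:
            n_extreme += 1
    return n_extreme / total
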