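"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately written with different algorithms/data structures than the
package implementations so they constitute a second route to the same
quantities.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def ecdf_survivor(times, t):
    """1 - ECDF of event times at t (no-censoring survival oracle)."""
    times = np.asarray(times, dtype=float)
    return 1.0 - np.mean(times <= t)


def logrank_chi2_oracle(times, events, group):
    """Log-rank statistic via explicit per-event-time set arithmetic."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group, dtype=bool)
    o1 = e1 = v = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int((events & (times == t)).sum())
        n1 = int((at_risk & group).sum())
        d1 = int((events & (times == t) & group).sum())
        o1 += d1
        e1 += n1 * d / n
        if n > 1:
            v += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0
    return (o1 - e1) ** 2 / v


def permutation_pvalue(times, events, group, statistic=logrank_chi2_oracle):
    """Exact permutation p over all label assignments of the same sizes."""
    n = len(times)
    n1 = int(np.asarray(group, dtype=bool).sum())
    observed = statistic(times, events, group)
    hits = total = 0
    for idx in combinations(range(n), n1):
        g = np.zeros(n, dtype=bool)
        g[list(idx)] = True
        total += 1
        if statistic(times, events, g) >= observed - 1e-12:
            hits += 1
    return hits / total


def hypergeom_tail_oracle(N, K, n, k):
    """P[X >= k] by direct summation of the hypergeometric pmf."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total


def bh_oracle(p):
    """Step-up closed form: cummin over m * p_(i) / i, mapped back."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        out[i] = running_min
    return out


def chisq_upper_tail(x):
    return float(stats.chi2.sf(x, df=1))
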