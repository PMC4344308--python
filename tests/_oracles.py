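"""Independent brute-force oracles shared by the test modules.

These deliberately avoid scipy so they constitute a second code path:
exact tail probabilities by direct enumeration with integer combinatorics.
"""

import itertools
import math


def enumerate_fisher_tail(counts):
    """Exact hypergeometric upper tail P(X >= a) by explicit summation."""
    a = counts[0][0]
    K = counts[0][0] + counts[1][0]
    n = counts[0][0] + counts[0][1]
    M = sum(counts[0]) + sum(counts[1])
    denom = math.comb(M, n)
    hi = min(n, K)
    return sum(
        math.comb(K, k) * math.comb(M - K, n - k) / denom
        for k in range(a, hi + 1)
    )


def enumerate_mannwhitney(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    the pooled values to the two groups."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        gt = sum(1 for xi in xs for yi in ys if xi > yi)
        eq = sum(1 for xi in xs for yi in ys if xi == yi)
        return gt + 0.5 * eq

    mean_u = nx * len(y) / 2
    dev_obs = abs(u_stat(x, y) - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        in_x = set(combo)
        xs = [pooled[i] for i in in_x]
        ys = [pooled[i] for i in range(len(pooled)) if i not in in_x]
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total
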