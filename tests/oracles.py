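"""Independent brute-force reference implementations used only by tests.

Everything here is written in plain Python against the textbook definitions
(explicit rank assignment, explicit step-down loops) so it shares no code
path with the package implementations it cross-checks.
"""

import math


def average_ranks(values):
    """Average ranks (1-based) with ties sharing the mean of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_wallis_oracle(groups):
    """H statistic with the standard tie correction, from first principles."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos: pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    t_sum = sum(c**3 - c for c in counts.values() if c > 1)
    if t_sum:
        h /= 1.0 - t_sum / (n**3 - n)
    return h


def holm_oracle(pvalues):
    """Holm step-down adjusted p-values by the explicit definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_max = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, (m - rank) * pvalues[i])
        running_max = max(running_max, val)
        adjusted[i] = running_max
    return adjusted


def bonferroni_oracle(pvalues):
    m = len(pvalues)
    return [min(1.0, m * p) for p in pvalues]


def spearman_oracle(x, y):
    """Spearman rho = Pearson correlation of the average ranks."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def median_oracle(values):
    """Median by sorting, midpoint of the two central values for even n."""
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def beta_moments(a, b):
    """Mean and variance of a beta distribution with shapes (a, b)."""
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1))
    return mean, var
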