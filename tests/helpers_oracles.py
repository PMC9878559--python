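"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the mathematical definitions with explicit
loops, deliberately sharing no code with the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np


def brute_anova_f(x, y) -> float:
    """One-way F for two groups from explicit sums of squares."""
    g0 = [v for v, t in zip(x, y) if t == 0]
    g1 = [v for v, t in zip(x, y) if t == 1]
    n = len(x)
    grand = sum(x) / n
    m0 = sum(g0) / len(g0)
    m1 = sum(g1) / len(g1)
    ssb = len(g0) * (m0 - grand) ** 2 + len(g1) * (m1 - grand) ** 2
    ssw = sum((v - m0) ** 2 for v in g0) + sum((v - m1) ** 2 for v in g1)
    if ssw == 0:
        return 0.0 if ssb == 0 else math.inf
    return (ssb / 1.0) / (ssw / (n - 2))


def brute_mi_from_bins(u, v) -> float:
    """Plug-in MI (nats) from two discrete vectors via the double sum."""
    n = len(u)
    total = 0.0
    for a in set(u):
        for b in set(v):
            p_ab = sum(1 for x, y in zip(u, v) if x == a and y == b) / n
            if p_ab == 0:
                continue
            p_a = sum(1 for x in u if x == a) / n
            p_b = sum(1 for y in v if y == b) / n
            total += p_ab * math.log(p_ab / (p_a * p_b))
    return total


def brute_quantile_bins(x, bins) -> list[int]:
    """Mirror of the package's binning rule, from the definition."""
    edges = np.quantile(np.asarray(x, dtype=float),
                        [i / bins for i in range(bins + 1)])
    inner = sorted(set(edges[1:-1].tolist()))
    out = []
    for v in x:
        # values equal to an inner edge belong to the upper bin
        out.append(sum(1 for e in inner if v >= e))
    return out


def _avg_ranks(x) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y) -> float:
    """Pearson correlation of average ranks, from the definition."""
    rx, ry = _avg_ranks(list(x)), _avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


def brute_recurrence_matrix(series, radius=0.2, normalize=True):
    x = [float(v) for v in series]
    n = len(x)
    if normalize:
        mean = sum(x) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
        x = [0.0] * n if sd == 0 else [(v - mean) / sd for v in x]
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    eps = radius * sd
    return [[abs(x[i] - x[k]) <= eps for k in range(n)] for i in range(n)]


def brute_diagonal_census(r, jmin=2) -> dict[int, int]:
    """Walk every off-main diagonal and tally maximal run lengths."""
    n = len(r)
    counts: dict[int, int] = {}
    for offset in range(-(n - 1), n):
        if offset == 0:
            continue  # main diagonal excluded
        cells = []
        for i in range(n):
            k = i + offset
            if 0 <= k < n:
                cells.append(r[i][k])
        run = 0
        for val in cells + [False]:
            if val:
                run += 1
            elif run:
                if run >= jmin:
                    counts[run] = counts.get(run, 0) + 1
                run = 0
    return counts


def brute_entropy(counts) -> float:
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def brute_confusion(truth, pred):
    tp = tn = fp = fn = 0
    for t, p in zip(truth, pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 0:
            tn += 1
        elif t == 0 and p == 1:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
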