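"""Independent brute-force oracles used by the test suite.

These deliberately use naive enumeration, separate from the library's
implementations, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def shorth_midpoint_bruteforce(values) -> float:
    """Enumerate every interval [x_i, x_j] covering >= h = floor(n/2)+1
    points; pick the narrowest (ties: smallest left endpoint); return its
    midpoint."""
    x = sorted(float(v) for v in values)
    n = len(x)
    h = n // 2 + 1
    best = None
    for i in range(n):
        for j in range(i, n):
            covered = j - i + 1
            if covered < h:
                continue
            width = x[j] - x[i]
            key = (width, x[i])
            if best is None or key < best[0]:
                best = (key, (x[i] + x[j]) / 2.0)
    return best[1]


def bh_bruteforce(p) -> list[float]:
    """Literal step-up: padj_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = [float(v) for v in p]
    m = len(p)
    order = sorted(range(m), key=lambda k: p[k])
    adj_sorted = []
    for rank_i in range(m):
        candidates = [m * p[order[rank_j]] / (rank_j + 1)
                      for rank_j in range(rank_i, m)]
        adj_sorted.append(min(1.0, min(candidates)))
    out = [0.0] * m
    for rank, k in enumerate(order):
        out[k] = adj_sorted[rank]
    return out


def ks_statistic_bruteforce(a, b) -> float:
    """sup |F1 - F2| over the pooled sample points."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    f1 = np.searchsorted(a, grid, side="right") / a.size
    f2 = np.searchsorted(b, grid, side="right") / b.size
    return float(np.max(np.abs(f1 - f2)))
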