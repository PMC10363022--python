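"""Naive reference implementations used as independent oracles.

Deliberately written as explicit loops from the statistic definitions;
they stay independent of the vectorized code paths they validate.
"""

from __future__ import annotations

import math

import numpy as np


def zscore_brute(x):
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)  # population sd
    return [(v - mean) / sd for v in x]


def morans_i_brute(x, W) -> float:
    """Double loop over the Moran's I definition."""
    W = np.asarray(W, dtype=float)
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    z = [v - mean for v in x]
    s0 = sum(W[i][j] for i in range(n) for j in range(n))
    num = sum(W[i][j] * z[i] * z[j] for i in range(n) for j in range(n))
    den = sum(v * v for v in z)
    return n / s0 * num / den


def local_l_brute(x, y, W):
    """Triple loop: per-spot product of neighbor-weighted z-score sums."""
    W = np.asarray(W, dtype=float)
    zx = zscore_brute(x)
    zy = zscore_brute(y)
    n = len(zx)
    out = []
    for i in range(n):
        lag_x = sum(W[i][j] * zx[j] for j in range(n))
        lag_y = sum(W[i][j] * zy[j] for j in range(n))
        out.append(lag_x * lag_y)
    return out


def global_l_brute(x, y, W) -> float:
    values = local_l_brute(x, y, W)
    return sum(values) / len(values)


def bh_brute(p):
    """Benjamini-Hochberg step-up, applied literally to the definition."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
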