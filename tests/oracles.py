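"""Independent brute-force oracles used to pin expected values.

These deliberately avoid the code paths they check: integer/Fraction
arithmetic and exhaustive enumeration only.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exact integer enumeration over fixed margins.

    Table weights C(r1,k)·C(r2,c1−k) are exact integers, so "no more
    probable than observed" is decided without any floating point.
    """
    r1, r2, c1 = a + b, c + d, a + c

    def weight(k: int) -> int:
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    ks = [k for k in range(0, r1 + 1) if 0 <= c1 - k <= r2]
    w_obs = weight(a)
    total = sum(weight(k) for k in ks)
    tail = sum(w for k in ks if (w := weight(k)) <= w_obs)
    return Fraction(tail, total)


def _midranks(values) -> list[Fraction]:
    """Mid-ranks as exact fractions, by sorting and averaging tied runs."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks: list[Fraction] = [Fraction(0)] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = Fraction(i + 1 + j + 1, 2)
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def wilcoxon_oracle(x, y) -> Fraction:
    """Two-sided exact rank-sum p by enumerating all C(n+m, n) assignments.

    Two-sided convention: double the smaller of P(W ≤ w_obs), P(W ≥ w_obs),
    capped at 1.  Exact Fraction arithmetic throughout.
    """
    pooled = list(x) + list(y)
    ranks = _midranks(pooled)
    n = len(x)
    w_obs = sum(ranks[:n], Fraction(0))
    le = ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        w = sum((ranks[i] for i in combo), Fraction(0))
        total += 1
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    p = 2 * Fraction(min(le, ge), total)
    return min(p, Fraction(1))


def mean_loop_oracle(image: np.ndarray, mask: np.ndarray) -> float:
    """Per-pixel python-loop mean over a mask."""
    total = 0.0
    count = 0
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                total += float(image[i, j])
                count += 1
    return total / count


def pixel_sum_cer_oracle(image: np.ndarray, plate: np.ndarray, cell: np.ndarray, bg: float) -> float:
    """CER from raw per-pixel sums over the constructed masks."""
    chrom = mean_loop_oracle(image, plate)
    whole = mean_loop_oracle(image, cell)
    return (chrom - bg) / (whole - bg)
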