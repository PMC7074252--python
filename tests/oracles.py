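"""Independent brute-force oracles shared across the test suite.

Everything here is deliberately naive — exact rational arithmetic and
exhaustive enumeration — and never calls into the implementation paths it
is used to check.
"""

import math
from fractions import Fraction

import numpy as np


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg two-sided p by enumeration over all feasible
    heterozygote counts, in exact rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (rare - h) // 2
        b = (2 * n - rare - h) // 2
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(a) * math.factorial(h) * math.factorial(b),
        )
    total = sum(weights.values())
    obs = weights[n_het]
    return float(min(1, sum(w for w in weights.values() if w <= obs) / total))


def fisher_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p for [[a, b], [c, d]] by exhaustive enumeration
    with exact integer weights."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(lo, hi + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def fisher_2x3_oracle(table: np.ndarray) -> Fraction:
    """Exact conditional p for a 2x3 table by full enumeration."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    weights = {}
    for t00 in range(min(r[0], c[0]) + 1):
        for t01 in range(min(r[0] - t00, c[1]) + 1):
            t02 = r[0] - t00 - t01
            if t02 > c[2]:
                continue
            weights[(t00, t01)] = (
                math.comb(c[0], t00)
                * math.comb(c[1], t01)
                * math.comb(c[2], t02)
            )
    total = sum(weights.values())
    obs = weights[(table[0, 0], table[0, 1])]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def all_2x2_tables(max_total: int):
    """Every 2x2 table of non-negative counts with 1 <= total <= max_total."""
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c
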