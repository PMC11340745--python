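"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid every code path they verify: stable pairs by a
double loop over unordered pairs, Fisher's exact test by exhaustive
enumeration of all 2x2 tables with the observed margins in exact rational
arithmetic.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def brute_force_stable_pairs(values: np.ndarray, feature_ids: list[str]) -> set[tuple[str, str]]:
    """All oriented pairs (upper, lower) with upper > lower strictly in every column."""
    out: set[tuple[str, str]] = set()
    for i, j in combinations(range(len(feature_ids)), 2):
        if np.all(values[i] > values[j]):
            out.add((feature_ids[i], feature_ids[j]))
        elif np.all(values[j] > values[i]):
            out.add((feature_ids[j], feature_ids[i]))
    return out


def brute_force_consistency(
    pairs: list[tuple[str, str]], values: np.ndarray, feature_ids: list[str]
) -> dict[tuple[str, str], float]:
    """Per-pair fraction of columns maintaining upper > lower."""
    idx = {f: i for i, f in enumerate(feature_ids)}
    out = {}
    for u, l in pairs:
        kept = sum(1 for j in range(values.shape[1]) if values[idx[u], j] > values[idx[l], j])
        out[(u, l)] = kept / values.shape[1]
    return out


def fisher_exhaustive(n1: int, m1: int, n2: int, m2: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed margins.

    Sums the exact hypergeometric probabilities of every table no more
    probable than the observed one (with the conventional tiny relative
    tolerance for probability ties).
    """
    r1, r2, c1 = n1 + m1, n2 + m2, n1 + n2
    denom = comb(r1 + r2, c1)
    p_obs = Fraction(comb(r1, n1) * comb(r2, c1 - n1), denom)
    threshold = p_obs * (1 + Fraction(1, 10**7))
    total = Fraction(0)
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_a = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
        if p_a <= threshold:
            total += p_a
    return float(total)


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for the overlap of fixed-size draws, in exact rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)
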