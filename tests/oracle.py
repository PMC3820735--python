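"""Independent brute-force oracles used by the test suite.

These stay deliberately independent of the package's scipy-based paths:
tail probabilities are computed by exact enumeration over all draws.
"""

from fractions import Fraction
from itertools import combinations


def enumerate_hypergeom_tails(N: int, K: int, n: int, x: int):
    """(P(X >= x), P(X <= x)) for X ~ Hypergeometric(N, K, n), by
    enumerating all C(N, n) draws from an urn with K successes."""
    population = [1] * K + [0] * (N - K)
    total = upper = lower = 0
    for draw in combinations(range(N), n):
        total += 1
        successes = sum(population[i] for i in draw)
        if successes >= x:
            upper += 1
        if successes <= x:
            lower += 1
    return Fraction(upper, total), Fraction(lower, total)


def binomial_tail_upper(m: int, q: Fraction, x: int) -> Fraction:
    """P(X >= x) for X ~ Binomial(m, q) by direct summation."""
    from math import comb

    q = Fraction(q)
    return sum(
        comb(m, j) * q**j * (1 - q) ** (m - j) for j in range(x, m + 1)
    )
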