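"""Independent brute-force oracles used to check the implementation."""

from fractions import Fraction
from math import comb


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p by enumerating the support.

    Sums the exact hypergeometric probabilities, as rationals, of every
    table with the observed margins whose first cell is >= a.
    """
    row, col, n = a + b, a + c, a + b + c + d
    hi = min(row, col)
    denom = comb(n, col)
    total = Fraction(0)
    for x in range(a, hi + 1):
        total += Fraction(comb(row, x) * comb(n - row, col - x), denom)
    return float(total)
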