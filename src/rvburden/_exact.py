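"""Exact hypergeometric tail evaluation shared by the burden and
enrichment tests.  Integer binomial-coefficient arithmetic; the only
rounding is the final conversion to float."""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb


@lru_cache(maxsize=500_000)
def hypergeom_tail(n1: int, n2: int, k: int, a: int) -> Fraction:
    """P(X >= a) for X ~ Hypergeometric(N = n1 + n2, K = k, draws = n1).

    X counts successes among the n1 draws when k of the N objects are
    successes.  Returned as an exact Fraction; callers convert to float.
    """
    if a <= max(0, k - n2):
        return Fraction(1)
    denom = comb(n1 + n2, k)
    num = sum(comb(n1, x) * comb(n2, k - x) for x in range(a, min(n1, k) + 1))
    return Fraction(num, denom)
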