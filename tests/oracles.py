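"""Independent brute-force oracles used only by the tests.

The 2x2 oracle enumerates Fisher's noncentral hypergeometric distribution
directly from exact integer binomial coefficients (``math.comb``), with
probabilities as ``fractions.Fraction`` at psi = 1, entirely independent of
the log-space implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def support(a: int, b: int, c: int, d: int) -> range:
    r1, r2, c1 = a + b, c + d, a + c
    return range(max(0, c1 - r2), min(c1, r1) + 1)


def exact_pmf_psi1(a: int, b: int, c: int, d: int) -> dict[int, Fraction]:
    """Exact conditional pmf at odds ratio 1 (central hypergeometric)."""
    r1, r2, c1 = a + b, c + d, a + c
    weights = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k)) for k in support(a, b, c, d)}
    total = sum(weights.values())
    return {k: w / total for k, w in weights.items()}


def exact_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-sided p, exact integer arithmetic.

    The tie tolerance mirrors the implementation's relative epsilon of 1e-7
    as an exact integer comparison: keep k with w_k * 10^7 <= w_a * (10^7+1).
    """
    r1, r2, c1 = a + b, c + d, a + c
    ks = list(support(a, b, c, d))
    w = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in ks}
    scale = 10**7
    num = sum(wk for wk in w.values() if wk * scale <= w[a] * (scale + 1))
    return float(Fraction(num, sum(w.values())))


def noncentral_tail(a: int, b: int, c: int, d: int, psi: float, side: str) -> float:
    """P(A >= a) or P(A <= a) at noncentrality psi (float weights on exact combs)."""
    r1, r2, c1 = a + b, c + d, a + c
    ks = list(support(a, b, c, d))
    w = [math.comb(r1, k) * math.comb(r2, c1 - k) * psi ** (k - ks[0]) for k in ks]
    total = sum(w)
    if side == "ge":
        num = sum(wi for k, wi in zip(ks, w) if k >= a)
    else:
        num = sum(wi for k, wi in zip(ks, w) if k <= a)
    return num / total


def noncentral_mean(a: int, b: int, c: int, d: int, psi: float) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    ks = list(support(a, b, c, d))
    w = [math.comb(r1, k) * math.comb(r2, c1 - k) * psi ** (k - ks[0]) for k in ks]
    total = sum(w)
    return sum(k * wi for k, wi in zip(ks, w)) / total


def all_tables(max_margin: int):
    """Every 2x2 table whose four margins are all <= max_margin and positive."""
    n = max_margin
    for r1 in range(n + 1):
        for a in range(r1 + 1):
            b = r1 - a
            for c in range(n - a + 1):
                for d in range(min(n - c, n - b) + 1):
                    if (a + b) and (c + d) and (a + c) and (b + d):
                        yield a, b, c, d
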