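"""Exact conditional inference for 2x2 contingency tables.

Conditioned on both margins, the count in the focal cell of a 2x2 table
follows Fisher's noncentral hypergeometric distribution with noncentrality
equal to the odds ratio psi.  This module provides the three quantities a
"two-tailed Fisher's exact test" report is built from:

* the two-sided p-value at psi = 1 (point-probability ordering),
* the conditional maximum-likelihood estimate of the odds ratio
  (the psi at which the conditional mean of the focal cell equals the
  observed count), and
* the exact central confidence interval obtained by inverting the two
  one-sided tail tests at (1 - conf_level)/2 each.

This matches the behaviour of R's ``fisher.test``.  All tail sums are
computed in log space over the conditional support, vectorized with numpy,
so tables whose support spans millions of values (count-per-bp enrichment
tables over whole chromosome arms) remain tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = ["TwoByTwo", "EnrichmentResult", "fisher_exact"]

# relative slack when collecting outcomes "at most as probable" as the
# observed one; same convention as R's fisher.test
_P_REL_EPS = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 table of non-negative counts.

    Layout: rows are the two classes, columns success/failure, with ``a``
    the focal cell (row 1 successes)::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty (all margins zero)")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def col2(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact odds-ratio inference for one 2x2 table."""

    or_cmle: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    conf_level: float


class _Support:
    """Conditional support of the focal cell and its log base weights.

    log P(A = k | margins; psi)  is proportional to
    ``logC(row1, k) + logC(row2, col1 - k) + k * log(psi)``;
    the k-independent part is precomputed once per table.
    """

    def __init__(self, t: TwoByTwo):
        self.lo = max(0, t.col1 - t.row2)
        self.hi = min(t.col1, t.row1)
        self.k = np.arange(self.lo, self.hi + 1, dtype=np.float64)
        self.base = (
            _log_binom(t.row1, self.k)
            + _log_binom(t.row2, t.col1 - self.k)
        )

    def _weights(self, log_psi: float) -> np.ndarray:
        """exp weights rescaled by their max (safe against overflow)."""
        w = self.base + self.k * log_psi
        np.subtract(w, w.max(), out=w)
        return np.exp(w, out=w)

    def logpmf(self, log_psi: float) -> np.ndarray:
        w = self.base + self.k * log_psi
        m = w.max()
        total = m + math.log(float(np.exp(w - m).sum()))
        return w - total

    def tail_ge(self, a: int, log_psi: float) -> float:
        """P(A >= a) under noncentrality exp(log_psi)."""
        e = self._weights(log_psi)
        return float(e[a - self.lo :].sum() / e.sum())

    def tail_le(self, a: int, log_psi: float) -> float:
        e = self._weights(log_psi)
        return float(e[: a - self.lo + 1].sum() / e.sum())

    def mean(self, log_psi: float) -> float:
        e = self._weights(log_psi)
        return float(np.dot(e, self.k) / e.sum())


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _solve(f, target: float, increasing: bool) -> float:
    """Root of the monotone ``f(log_psi) - target`` by bracket expansion + Brent."""

    def g(x: float) -> float:
        return f(x) - target

    lo, hi = -1.0, 1.0
    glo, ghi = g(lo), g(hi)
    for _ in range(200):
        if glo * ghi <= 0:
            break
        # expand toward the side the root must lie on (f is monotone)
        if (glo > 0) == increasing:
            lo *= 2.0
            glo = g(lo)
        else:
            hi *= 2.0
            ghi = g(hi)
    else:  # pragma: no cover - tails are monotone, bracket always found
        raise RuntimeError("failed to bracket root for exact CI")
    return brentq(g, lo, hi, xtol=1e-11, rtol=8.9e-16)


def fisher_exact(table: TwoByTwo, conf_level: float = 0.95) -> EnrichmentResult:
    """Exact two-sided Fisher test with conditional-MLE OR and central CI.

    Parameters
    ----------
    table
        The 2x2 table; ``table.a`` is the focal cell.
    conf_level
        Coverage of the central confidence interval (equal tail mass
        ``(1 - conf_level)/2`` excluded on each side).

    Returns
    -------
    EnrichmentResult
        ``or_cmle`` is 0 or ``inf`` when the focal cell sits at an end of
        its conditional support (a zero cell); the matching CI bound is
        0 / ``inf`` as well, never an exception.

    Raises
    ------
    ValueError
        If a margin of the table is zero (the conditional distribution is
        degenerate and the odds ratio is undefined).
    """
    if not isinstance(table, TwoByTwo):
        table = TwoByTwo(*table)
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must be in (0, 1), got {conf_level}")
    if min(table.row1, table.row2, table.col1, table.col2) == 0:
        raise ValueError("a margin of the table is zero; odds ratio undefined")

    sup = _Support(table)
    a = table.a
    alpha = (1.0 - conf_level) / 2.0

    # two-sided p at psi = 1: total mass of outcomes no more probable
    # than the observed one
    e = sup._weights(0.0)
    pmf = e / e.sum()
    p_two = float(pmf[pmf <= pmf[a - sup.lo] * (1.0 + _P_REL_EPS)].sum())
    p_two = min(1.0, p_two)

    if sup.lo == sup.hi:  # degenerate support cannot happen with nonzero margins
        raise ValueError("degenerate conditional support")  # pragma: no cover

    # conditional MLE: E_psi[A] = a, monotone increasing in psi
    if a == sup.lo:
        or_cmle = 0.0
    elif a == sup.hi:
        or_cmle = math.inf
    else:
        or_cmle = math.exp(_solve(sup.mean, float(a), increasing=True))

    # central CI by inverting the one-sided exact tests
    if a == sup.lo:
        ci_low = 0.0
    else:
        ci_low = math.exp(_solve(lambda x: sup.tail_ge(a, x), alpha, increasing=True))
    if a == sup.hi:
        ci_high = math.inf
    else:
        ci_high = math.exp(_solve(lambda x: sup.tail_le(a, x), alpha, increasing=False))

    return EnrichmentResult(
        or_cmle=or_cmle,
        ci_low=ci_low,
        ci_high=ci_high,
        p_two_sided=p_two,
        conf_level=conf_level,
    )
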