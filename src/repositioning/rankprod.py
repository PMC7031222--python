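"""Exact and approximate tail probabilities of the rank-product statistic.

The rank product of ``k`` query genes inside a ranked list of ``n`` genes is
``RP = r_1 * r_2 * ... * r_k``.  Under the with-replacement null model the
ranks are i.i.d. uniform on ``{1..n}``, so the left-tail p-value is a pure
counting problem::

    P(RP <= x) = |{(r_1..r_k) in {1..n}^k : prod r_i <= x}| / n^k

The count is evaluated exactly in integer arithmetic by the recursion

    T(k, x) = sum_{r=1}^{min(n, x)} T(k-1, floor(x/r)),   T(0, x) = 1 for x >= 1

memoized on the distinct values of ``floor(x/d)`` and accelerated by grouping
runs of ``r`` that share the same quotient (divisor blocking).  The cost is
governed by the quotient-set size, roughly ``2*sqrt(min(x, n^k))`` states, so
exact evaluation is cheap precisely in the decision-relevant left tail (small
products) and grows infeasible in the bulk of the distribution.  There the
continuous approximation takes over: with ``U_i = r_i/n`` treated as uniform
on (0, 1], ``s = -sum ln U_i`` is Gamma(k, 1) distributed and

    P(RP <= x)  ~=  Q(k, s),    s = sum ln(n / r_i)

with ``Q`` the regularized upper incomplete gamma function.  The gamma tail
is accurate for moderate p at fixed rank fractions r/n; its *relative* error
grows as the far tail is entered (where the exact count is used instead).

``rankprod_pvalue`` dispatches between the two automatically based on an
a-priori bound on the memoization state count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaincc

__all__ = [
    "RankProductResult",
    "count_tuples_leq",
    "estimate_exact_cost",
    "rankprod_pvalue",
    "rankprod_pvalue_exact",
    "rankprod_pvalue_gamma",
    "DEFAULT_BUDGET",
]

#: default cap on memoization states for the auto-dispatched exact method
DEFAULT_BUDGET = 10**7

# smallest positive subnormal double; p-values are clamped into (0, 1]
_TINY = 5e-324

# int64-safe ceiling for the compiled k<=3 fast paths
_I64_MAX = 2**62


def _count2_py(n: int, x: int) -> int:
    # sum_{r<=min(n,x)} min(n, x//r), runs of equal quotient taken in blocks
    lim = n if n < x else x
    total = 0
    r = 1
    while r <= lim:
        q = x // r
        r2 = x // q
        if r2 > lim:
            r2 = lim
        total += (r2 - r + 1) * (q if q < n else n)
        r = r2 + 1
    return total


def _count3_py(n: int, x: int) -> int:
    lim = n if n < x else x
    total = 0
    r = 1
    while r <= lim:
        q = x // r
        r2 = x // q
        if r2 > lim:
            r2 = lim
        total += (r2 - r + 1) * _count2_py(n, q)
        r = r2 + 1
    return total


def _count_ladder_py(k: int, n: int, x: int):
    """Bottom-up evaluation of T(k, n, x) over the quotient set of ``x``.

    The reachable arguments of the recursion are exactly the distinct values
    of ``x // d``; values <= sqrt(x) are tabulated directly, larger ones are
    indexed by their divisor.  Each level j reuses only level j-1, so the
    whole computation is two arrays of length ~sqrt(x) per level.
    """
    s = int(np.sqrt(x))
    while (s + 1) * (s + 1) <= x:
        s += 1
    while s * s > x:
        s -= 1
    small = np.empty(s + 1, dtype=np.int64)  # small[v] = T_j(v), 1 <= v <= s
    big = np.empty(s + 1, dtype=np.int64)  # big[d] = T_j(x // d), 1 <= d <= s
    for v in range(1, s + 1):
        small[v] = v if v < n else n
    for d in range(1, s + 1):
        q = x // d
        big[d] = q if q < n else n
    npow = np.int64(n)
    overflow_cap = np.int64(2) ** 62
    for _j in range(2, k + 1):
        if npow < overflow_cap // n:
            npow = npow * n
        else:
            npow = overflow_cap  # saturation shortcut disabled from here on
        new_small = np.empty(s + 1, dtype=np.int64)
        new_big = np.empty(s + 1, dtype=np.int64)
        for v in range(1, s + 1):
            if v >= npow:
                new_small[v] = npow
                continue
            lim = n if n < v else v
            total = np.int64(0)
            r = 1
            while r <= lim:
                q = v // r
                r2 = v // q
                if r2 > lim:
                    r2 = lim
                total += (r2 - r + 1) * small[q]
                r = r2 + 1
            new_small[v] = total
        for d in range(s, 0, -1):
            v = x // d
            if v <= s:
                new_big[d] = new_small[v]
                continue
            if v >= npow:
                new_big[d] = npow
                continue
            lim = n if n < v else v
            total = np.int64(0)
            r = 1
            while r <= lim:
                q = v // r
                r2 = v // q
                if r2 > lim:
                    r2 = lim
                total += (r2 - r + 1) * (small[q] if q <= s else big[x // q])
                r = r2 + 1
            new_big[d] = total
        small, big = new_small, new_big
    return small[x] if x <= s else big[1]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _count2_fast = njit(cache=False)(_count2_py)

    @njit(cache=False)
    def _count3_fast(n, x):  # same blocking loop, compiled inner sum
        lim = n if n < x else x
        total = 0
        r = 1
        while r <= lim:
            q = x // r
            r2 = x // q
            if r2 > lim:
                r2 = lim
            total += (r2 - r + 1) * _count2_fast(n, q)
            r = r2 + 1
        return total

    _count_ladder = njit(cache=False)(_count_ladder_py)
except ImportError:  # pragma: no cover
    _count2_fast = _count2_py
    _count3_fast = _count3_py
    _count_ladder = _count_ladder_py


def count_tuples_leq(k: int, n: int, x: int) -> int:
    """Count k-tuples over {1..n} whose product does not exceed ``x``.

    Exact integer arithmetic throughout; the result is an arbitrary-precision
    integer in ``[0, n^k]``.

    Parameters
    ----------
    k : number of ranks (>= 0).
    n : universe size (>= 1).
    x : product threshold (>= 0; values above ``n^k`` saturate).
    """
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if x < 1:
        return 0
    if k == 0:
        return 1
    memo: dict[tuple[int, int], int] = {}
    return _count_rec(k, n, int(x), memo)


def _int64_safe(k: int, n: int, x: int) -> bool:
    """True when no intermediate count of the int64 fast paths can overflow.

    Intermediate values at level j are bounded by min(n^j, D_j(v)) with the
    rigorous bound D_j(v) <= v * (1 + ln v)^(j-1); int64 arithmetic is safe
    when every level's bound stays under 2^61.
    """
    if x >= _I64_MAX or n >= 2**31:
        return False
    limit = 2.0**61
    log_term = 1.0 + math.log(x)
    nf = float(n)
    for j in range(2, k + 1):
        if min(nf**j, x * log_term ** (j - 1)) >= limit:
            return False
    return True


def _count_rec(k: int, n: int, x: int, memo: dict) -> int:
    if x < 1:
        return 0
    if k == 1:
        return n if n < x else x
    cap = n**k
    if x >= cap:
        return cap
    if _int64_safe(k, n, x):
        if k == 2:
            return int(_count2_fast(n, x))
        if k == 3:
            return int(_count3_fast(n, x))
        return int(_count_ladder(k, n, x))
    key = (k, x)
    cached = memo.get(key)
    if cached is not None:
        return cached
    if k == 2:
        total = _count2_py(n, x)
    else:
        total = 0
        lim = n if n < x else x
        r = 1
        while r <= lim:
            q = x // r
            r2 = x // q
            if r2 > lim:
                r2 = lim
            total += (r2 - r + 1) * _count_rec(k - 1, n, q, memo)
            r = r2 + 1
    memo[key] = total
    return total


def estimate_exact_cost(k: int, n: int, x: int) -> int:
    """A-priori bound on memo states for ``count_tuples_leq(k, n, x)``.

    Distinct floor values of ``x`` under repeated integer division number
    about ``2*sqrt(x)`` (saturating at ``n^k``), times the recursion depth.
    """
    if x < 1 or k <= 1:
        return k + 1
    cap = n**k
    xe = x if x < cap else cap
    return 2 * math.isqrt(xe) * k


def _validate_ranks(ranks: Sequence[int], n: int) -> list[int]:
    if n < 1:
        raise ValueError(f"universe size n must be >= 1, got {n}")
    rs = list(ranks)
    if not rs:
        raise ValueError("at least one rank is required")
    for r in rs:
        if not isinstance(r, (int,)) or isinstance(r, bool):
            if not float(r).is_integer():
                raise ValueError(f"ranks must be integers, got {r!r}")
        ri = int(r)
        if not 1 <= ri <= n:
            raise ValueError(f"rank {ri} outside 1..{n}")
    # canonical order: the statistic is symmetric in the ranks, and sorting
    # makes the floating-point log-sum independent of input order
    return sorted(int(r) for r in rs)


def rankprod_pvalue_exact(ranks: Sequence[int], n: int) -> float:
    """Exact left-tail probability of the observed rank product.

    ``P(prod R_i <= prod ranks)`` with ``R_i`` i.i.d. uniform on ``{1..n}``,
    evaluated as an exact rational ``count / n^k`` and returned as a float.
    Always in ``[n^-k, 1]``.
    """
    rs = _validate_ranks(ranks, n)
    k = len(rs)
    rp = math.prod(rs)
    count = count_tuples_leq(k, n, rp)
    return float(Fraction(count, n**k))


def _log_stat(ranks: Sequence[int], n: int, midpoint: bool) -> float:
    if midpoint:
        return sum(math.log(n / (r - 0.5)) for r in ranks)
    return sum(math.log(n / r) for r in ranks)


def rankprod_pvalue_gamma(
    ranks: Sequence[int], n: int, midpoint: bool = False
) -> float:
    """Gamma-tail approximation ``Q(k, s)`` with ``s = sum ln(n/r_i)``.

    Treats each rank fraction ``r_i/n`` as continuous uniform on (0, 1], so
    ``s`` is Gamma(k, 1) under the null.  ``midpoint=True`` uses
    ``(r_i - 0.5)/n`` instead (a continuity correction, not the default).
    """
    rs = _validate_ranks(ranks, n)
    s = _log_stat(rs, n, midpoint)
    p = float(gammaincc(len(rs), s))
    return min(1.0, max(p, _TINY))


@dataclass(frozen=True)
class RankProductResult:
    """The rank-product statistic and its null tail probabilities."""

    k: int
    n: int
    rp: int  # product of the k ranks (arbitrary precision)
    log_stat: float  # s = sum ln(n / r_i)
    p_gamma: float
    p_exact: Optional[float]
    method_used: str  # "exact" | "gamma"

    @property
    def pvalue(self) -> float:
        """The p-value of the method actually used."""
        if self.method_used == "exact":
            assert self.p_exact is not None
            return self.p_exact
        return self.p_gamma


def rankprod_pvalue(
    ranks: Sequence[int],
    n: int,
    method: str = "auto",
    budget: int = DEFAULT_BUDGET,
    midpoint: bool = False,
) -> RankProductResult:
    """Rank-product tail probability with automatic method dispatch.

    ``method="auto"`` uses the exact count whenever its estimated memoization
    state count stays under ``budget``, otherwise the gamma approximation.
    """
    if method not in ("exact", "gamma", "auto"):
        raise ValueError(f"unknown method {method!r}")
    rs = _validate_ranks(ranks, n)
    k = len(rs)
    rp = math.prod(rs)
    s = _log_stat(rs, n, False)
    p_gamma = min(1.0, max(float(gammaincc(k, _log_stat(rs, n, midpoint))), _TINY))
    if method == "auto":
        method = "exact" if estimate_exact_cost(k, n, rp) <= budget else "gamma"
    p_exact = None
    if method == "exact":
        p_exact = float(Fraction(count_tuples_leq(k, n, rp), n**k))
    return RankProductResult(
        k=k, n=n, rp=rp, log_stat=s, p_gamma=p_gamma, p_exact=p_exact,
        method_used=method,
    )
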