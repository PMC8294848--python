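"""Exact counting and rank formulas.

All integer quantities are computed with arbitrary-precision arithmetic
(Python ints / sympy); no floating point enters a count.  The module covers:

- Stirling numbers of the second kind and poly-Bernoulli numbers with
  negative upper index, which count realizable field arrangements of
  two-module codes through the lonesum-matrix correspondence;
- the asymptotic growth of the two-module count;
- brute-force small-K counts and their growth-exponent check;
- Cover's function-counting formula for general-position inputs;
- the rank of grid-like input matrices via inclusion-exclusion over GCDs of
  period subsets, its real-valued-period extension through a resolution
  parameter q, and the d-dimensional capacity sum.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sympy.functions.combinatorial.numbers import stirling as _sympy_stirling

from gridplace.codebooks import make_grid_codebook
from gridplace.separability import is_realizable

__all__ = [
    "CountResult",
    "stirling2",
    "poly_bernoulli_neg",
    "count_two_module",
    "asymptotic_two_module",
    "smallK_count_bruteforce",
    "scaling_check",
    "cover_count",
    "rank_int",
    "rank_real",
    "rank_real_limit",
    "capacity_dd",
]


@dataclass(frozen=True)
class CountResult:
    """An exact count together with how it was obtained."""

    value: int
    method: str  # "closed_form" | "brute_force"
    parameters: dict

    def __int__(self) -> int:
        return self.value


def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k), exact."""
    if k > n or k < 0 or n < 0:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    return int(_sympy_stirling(n, k, kind=2))


def poly_bernoulli_neg(n: int, k: int) -> int:
    """Poly-Bernoulli number B_n^(-k) via the finite double-Stirling sum.

    ``B_n^(-k) = sum_j (j!)^2 S(n+1, j+1) S(k+1, j+1)``; symmetric in
    (n, k).  Counts lonesum n x k binary matrices.
    """
    if n < 0 or k < 0:
        raise ValueError("indices must be non-negative")
    return sum(
        math.factorial(j) ** 2 * stirling2(n + 1, j + 1) * stirling2(k + 1, j + 1)
        for j in range(min(n, k) + 1)
    )


def count_two_module(lam1: int, lam2: int) -> CountResult:
    """Number of realizable field arrangements (all K) for two modules.

    Equals the poly-Bernoulli number ``B_{lam2}^(-lam1)`` by the
    Young-diagram / lonesum-matrix correspondence; counts every labeling of
    the modular-one-hot codebook (lam1 * lam2 patterns), including the
    empty and full labelings.
    """
    if lam1 < 1 or lam2 < 1:
        raise ValueError("periods must be >= 1")
    value = poly_bernoulli_neg(lam2, lam1)
    return CountResult(value, "closed_form", {"lam1": lam1, "lam2": lam2})


_LOG2 = math.log(2.0)


def asymptotic_two_module(lam: int) -> float:
    """Leading-order two-module count for equal periods lam.

    ``(1/log 2) * (1/(1 - log 2)) * (2 lam)! / (2 log 2)^(2 lam)``,
    evaluated in the log domain so large lam do not overflow.
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    log_val = (
        -math.log(_LOG2)
        - math.log(1.0 - _LOG2)
        + math.lgamma(2 * lam + 1)
        - 2 * lam * math.log(2 * _LOG2)
    )
    return math.exp(log_val)


def log_asymptotic_two_module(lam: int) -> float:
    """Natural log of :func:`asymptotic_two_module` (safe for large lam)."""
    return (
        -math.log(_LOG2)
        - math.log(1.0 - _LOG2)
        + math.lgamma(2 * lam + 1)
        - 2 * lam * math.log(2 * _LOG2)
    )


# ---------------------------------------------------------------------------
# small-K counts and scaling


def smallK_count_bruteforce(
    periods: Sequence[int], K: int, cap: int = 2**20
) -> CountResult:
    """Exact count of realizable K-field arrangements over the full range.

    Enumerates all K-subsets of locations and tests each with the LP
    feasibility oracle.  Intended for small K (<= 4) and desk-scale ranges.
    """
    cb = make_grid_codebook(list(periods))
    P = cb.n_patterns
    if math.comb(P, K) > cap:
        raise ValueError(f"C({P},{K}) exceeds cap {cap}")
    count = 0
    y = np.zeros(P, dtype=np.int8)
    for idx in itertools.combinations(range(P), K):
        y[:] = 0
        y[list(idx)] = 1
        if is_realizable(cb, y):
            count += 1
    return CountResult(count, "brute_force", {"periods": list(periods), "K": K})


def scaling_check(
    M: int, lam_values: Sequence[int], K: int
) -> tuple[float, list[int]]:
    """Estimate the growth exponent of the K-field count in the period.

    Builds M-module grids with all periods near ``lam`` (coprime shifts so
    the full range stays the product), counts realizable K-field
    arrangements exactly, and fits ``log N_K ~ a log lam``.  For large
    periods the exponent approaches ``M + K - 1``.
    """
    counts = []
    for lam in lam_values:
        periods = _coprime_periods_near(lam, M)
        counts.append(smallK_count_bruteforce(periods, K).value)
    logs = np.log(np.asarray(counts, dtype=float))
    x = np.log(np.asarray(lam_values, dtype=float))
    a, _b = np.polyfit(x, logs, 1)
    return float(a), counts


def _coprime_periods_near(lam: int, M: int) -> list[int]:
    """M pairwise-coprime integers starting at lam (greedy search)."""
    periods = [lam]
    cand = lam + 1
    while len(periods) < M:
        if all(math.gcd(cand, p) == 1 for p in periods):
            periods.append(cand)
        cand += 1
    return periods


# ---------------------------------------------------------------------------
# Cover's counting function


def cover_count(P: int, N: int) -> int:
    """Cover's count of homogeneously separable dichotomies.

    ``C(P, N) = 2 * sum_{k=0}^{N-1} binom(P-1, k)`` for P patterns in
    general position in N dimensions.  The affine (free-threshold) case is
    ``cover_count(P, N + 1)``.  Equals ``2**P`` whenever ``P <= N``.
    """
    if P < 1 or N < 1:
        raise ValueError("P and N must be >= 1")
    return 2 * sum(math.comb(P - 1, k) for k in range(N))


# ---------------------------------------------------------------------------
# rank formulas


def rank_int(periods: Sequence[int]) -> int:
    """Rank of the integer-period grid input matrix, in closed form.

    Inclusion-exclusion over the GCDs of all k-element subsets of the
    periods::

        R = sum(lam_i) + sum_{k=2}^{M} (-1)^(k-1) sum_{S in subsets_k} GCD(S)

    For pairwise-coprime periods this reduces to ``Sigma - M + 1``.
    Degenerate period-1 modules are allowed (a constant cell, rank 1).
    """
    periods = [int(p) for p in periods]
    if not periods or any(p < 1 for p in periods):
        raise ValueError("periods must be positive integers")
    M = len(periods)
    total = sum(periods)
    for k in range(2, M + 1):
        sign = (-1) ** (k - 1)
        for sub in itertools.combinations(periods, k):
            total += sign * math.gcd(*sub)
    return total


def rank_real(periods: Sequence[float], q: int) -> int:
    """Rank at finite phase resolution q: ``rank_int(floor(q * lam_m))``."""
    if q < 1:
        raise ValueError("q must be >= 1")
    scaled = [int(math.floor(q * p)) for p in periods]
    if any(s < 1 for s in scaled):
        raise ValueError("q too small: a scaled period fell below 1")
    return rank_int(scaled)


def rank_real_limit(
    periods: Sequence[float], q_list: Sequence[int]
) -> list[tuple[int, float]]:
    """Ratio ``R_q / (q * Sigma)`` per resolution q.

    The ratio is bounded by 1 and approaches 1 from below as q grows, so
    the capacity of real-period codes converges to the sum of the periods.
    """
    sigma = float(sum(periods))
    return [(q, rank_real(periods, q) / (q * sigma)) for q in q_list]


def capacity_dd(periods: Sequence[float], d: int) -> float:
    """Generalized separating capacity in d spatial dimensions.

    ``Sigma_d = sum_m lam_m^d``: module m contributes ``lam_m^d`` cells
    (one-hot over its d-dimensional phase), and the capacity volume is the
    sum over modules.
    """
    if d not in (1, 2):
        raise ValueError("d must be 1 or 2")
    return float(sum(p**d for p in periods))
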