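"""Contiguous-separating-capacity experiments.

The contiguous-separating capacity ``l*`` of a place cell is the largest
number of contiguous locations over which *every* labeling is realizable.
For shift-generated codes (the grid code is produced by iterating a
block-cyclic permutation operator) this equals the rank of the input
matrix, so the exhaustive windowed enumeration performed here can be
cross-checked against the closed-form rank.

Because the grid code is translation invariant, the realizable fraction of
a window depends only on its length, not its origin; capacity sweeps use
the window starting at location 0 after that invariance is verified once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from gridplace.codebooks import Codebook, make_grid_codebook_2d, make_random
from gridplace.combinatorics import cover_count, rank_int
from gridplace.separability import count_realizable, is_realizable

__all__ = [
    "CapacityResult",
    "contiguous_capacity",
    "fraction_vs_range",
    "window_fraction",
    "translation_invariant_fraction",
    "random_comparison",
    "capacity_2d",
]

#: windowed enumeration tests at most 2**WINDOW_CAP labelings per window
WINDOW_CAP = 16


@dataclass
class CapacityResult:
    """Outcome of a capacity sweep."""

    l_star: int
    rank: int
    sigma: float
    fraction_curve: dict[int, float] = field(default_factory=dict)
    method: str = "enumeration"  # or "rank_only"


def window_fraction(cb: Codebook, start: int, length: int, K: int | str = "all") -> float:
    """Fraction of labelings of one contiguous window that are realizable.

    Only the window's patterns are constrained; the perceptron's output
    elsewhere is free.
    """
    X = cb.patterns[:, start : start + length]
    total = 2**length if K == "all" else math.comb(length, int(K))
    n_real = count_realizable(X, K=K)
    return n_real / total


def translation_invariant_fraction(cb: Codebook, length: int) -> list[float]:
    """Realizable fraction of every length-``length`` window (all origins).

    Windows wrap around the full range; for a translation-invariant code
    all entries are equal.
    """
    P = cb.n_patterns
    fracs = []
    for start in range(P):
        idx = [(start + i) % P for i in range(length)]
        X = cb.patterns[:, idx]
        fracs.append(count_realizable(X) / 2**length)
    return fracs


def contiguous_capacity(cb: Codebook, cap: int = WINDOW_CAP) -> CapacityResult:
    """Largest window length over which all labelings are realizable.

    Enumerates all ``2^l`` labelings of the window ``[0, l)`` for growing
    ``l`` and stops at the first length with an unrealizable labeling.  If
    the sweep would exceed the enumeration cap the result falls back to the
    closed-form rank with ``method="rank_only"``.
    """
    if cb.periods is None or cb.locations is None:
        raise ValueError("capacity needs a spatially embedded grid codebook")
    periods = [int(p) for p in cb.periods]
    R = rank_int(periods)
    sigma = float(sum(periods))
    if R + 1 > cap or R + 1 > cb.n_patterns:
        return CapacityResult(l_star=R, rank=R, sigma=sigma, method="rank_only")
    curve: dict[int, float] = {}
    l_star = 0
    for l in range(1, min(cb.n_patterns, cap) + 1):
        frac = window_fraction(cb, 0, l)
        curve[l] = frac
        if frac == 1.0:
            l_star = l
        else:
            break
    return CapacityResult(l_star=l_star, rank=R, sigma=sigma, fraction_curve=curve)


def fraction_vs_range(
    cb: Codebook, K: int | str = "all", cap: int = WINDOW_CAP,
    lengths: Sequence[int] | None = None,
) -> dict[int, float]:
    """Realizable fraction of the leading window as a function of its length."""
    if lengths is None:
        lengths = range(1, min(cb.n_patterns, cap) + 1)
    return {l: window_fraction(cb, 0, l, K=K) for l in lengths}


def random_comparison(
    n_cells: int,
    n_patterns_list: Sequence[int],
    nonneg: bool = False,
    n_trials: int = 20,
    seed: int = 0,
    cap: int = WINDOW_CAP,
) -> dict[int, tuple[float, float]]:
    """Empirical realizable fraction for random codebooks.

    Returns ``{P: (mean fraction, interquartile range)}`` over trials.  For
    unconstrained weights on general-position inputs the fraction matches
    Cover's count; the non-negative-weight constraint lowers it and makes it
    variable across input realizations.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[float, float]] = {}
    for P in n_patterns_list:
        if P > cap:
            raise ValueError(f"P={P} exceeds enumeration cap {cap}")
        fracs = []
        for _ in range(n_trials):
            cb = make_random(n_cells, P, rng)
            fracs.append(count_realizable(cb, nonneg=nonneg) / 2**P)
        fr = np.asarray(fracs)
        out[P] = (float(fr.mean()), float(np.subtract(*np.percentile(fr, [75, 25]))))
    return out


def cover_fraction(P: int, N: int) -> float:
    """Theoretical realizable fraction for general-position inputs
    (free threshold): ``cover_count(P, N + 1) / 2**P``."""
    return cover_count(P, N + 1) / 2**P


@dataclass
class Window2DResult:
    """Completeness of axis-aligned rectangular windows of a 2D grid code."""

    rank: int
    sigma_d: float
    complete: dict[tuple[int, int], bool] = field(default_factory=dict)


def capacity_2d(
    periods: Sequence[int],
    max_area: int = 12,
    cap: int = WINDOW_CAP,
) -> Window2DResult:
    """2D capacity: rank of the 2D grid code plus windowed completeness.

    Builds the 2D phase code (module m has ``lam_m^2`` cells), verifies the
    rank against ``Sigma_2 = sum lam_m^2``, and exhaustively tests every
    axis-aligned ``a x b`` rectangle with ``a*b <= min(max_area, cap)`` for
    realizability-completeness.
    """
    cb = make_grid_codebook_2d(periods)
    R = int(np.linalg.matrix_rank(cb.patterns.astype(float)))
    sigma_d = float(sum(int(p) ** 2 for p in periods))
    L = int(cb.meta["L"])
    area_cap = min(max_area, cap)
    complete: dict[tuple[int, int], bool] = {}
    for a in range(1, L + 1):
        for b in range(a, L + 1):
            if a * b > area_cap:
                continue
            idx = [x * L + y for x in range(a) for y in range(b)]
            X = cb.patterns[:, idx]
            ok = all(
                is_realizable(X, _bits(n, a * b)) for n in range(2 ** (a * b))
            )
            complete[(a, b)] = ok
    return Window2DResult(rank=R, sigma_d=sigma_d, complete=complete)


def _bits(n: int, width: int) -> np.ndarray:
    return np.array([(n >> i) & 1 for i in range(width)], dtype=np.int8)
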