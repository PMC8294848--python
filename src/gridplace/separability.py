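"""The perceptron engine: linear separability, margins, enumeration, sampling.

A place cell is modeled as a thresholded linear read-out
``y(x) = 1 if w.x - theta > 0 else 0``.  A binary labeling (dichotomy) of
the input patterns is *realizable* if some weights and threshold produce it.
Strict separation is decided through a scale-invariant unit-gap feasibility
linear program: we ask for ``w.x - theta >= +1`` on the field class and
``<= -1`` on the rest.  Any strictly separating pair can be rescaled to
satisfy these constraints, so the realizable set is unchanged while the
feasibility question becomes a closed linear program.

Margins follow the two-class-sum convention: the smallest point-to-boundary
distance of each class, summed over both classes.  At the hard-margin
optimum this equals ``2 / ||w||``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

from gridplace.codebooks import Codebook

__all__ = [
    "FieldArrangement",
    "PerceptronSolution",
    "is_realizable",
    "max_margin",
    "count_realizable",
    "enumerate_realizable",
    "is_lonesum",
    "labels_to_module_grid",
    "sample_realizable",
]

#: labelings enumerated exhaustively only below this count
ENUMERATION_CAP = 2**20

#: hard-margin SVM penalty (effectively infinite)
_HARD_C = 1e10


@dataclass
class FieldArrangement:
    """A binary labeling of patterns/locations; 1 marks a place field."""

    labels: np.ndarray
    window: tuple[int, int] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def K(self) -> int:
        return int(self.labels.sum())

    @property
    def field_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    def to_json_dict(self) -> dict:
        return {
            "fields": self.field_indices.tolist(),
            "n": int(self.labels.size),
            "window": list(self.window) if self.window else None,
        }


@dataclass
class PerceptronSolution:
    """Weights, threshold, and margin of a (candidate) separator."""

    weights: np.ndarray | None
    threshold: float | None
    feasible: bool
    margin: float = 0.0  # two-class-sum margin (2/||w|| at the optimum)
    geometric_margin: float = 0.0  # usual half-margin 1/||w||
    solver_status: str = ""


def _as_matrix(cb: Codebook | np.ndarray) -> np.ndarray:
    return cb.patterns if isinstance(cb, Codebook) else np.asarray(cb, dtype=float)


def _as_labels(fa: FieldArrangement | Sequence[int]) -> np.ndarray:
    labels = fa.labels if isinstance(fa, FieldArrangement) else np.asarray(fa)
    return labels.astype(np.int8)


def _unit_gap_lp(X: np.ndarray, y: np.ndarray, nonneg: bool, minimize_l1: bool):
    """Solve the unit-gap separation LP.

    Returns ``(status, w, theta)`` with status 0 (feasible) or 2
    (infeasible).  With ``minimize_l1`` the L1 norm of the weights is
    minimized, which yields a bounded, well-scaled separator instead of an
    arbitrary feasible point.
    """
    N, P = X.shape
    # variables z = [w_1..w_N, theta] (+ u_1..u_N if minimizing |w|)
    # y=1: -(w.x_j - theta) <= -1 ; y=0: w.x_j - theta <= -1
    sign = np.where(y == 1, -1.0, 1.0)
    A_sep = sign[:, None] * np.hstack([X.T, -np.ones((P, 1))])
    w_bound = (0, None) if nonneg else (None, None)
    if minimize_l1:
        eye = np.eye(N)
        A_ub = np.vstack(
            [
                np.hstack([A_sep, np.zeros((P, N))]),
                np.hstack([eye, np.zeros((N, 1)), -eye]),   # w - u <= 0
                np.hstack([-eye, np.zeros((N, 1)), -eye]),  # -w - u <= 0
            ]
        )
        b_ub = np.concatenate([-np.ones(P), np.zeros(2 * N)])
        c = np.concatenate([np.zeros(N + 1), np.ones(N)])
        bounds = [w_bound] * N + [(None, None)] + [(0, None)] * N
    else:
        A_ub = A_sep
        b_ub = -np.ones(P)
        c = np.zeros(N + 1)
        bounds = [w_bound] * N + [(None, None)]
    res = linprog(c=c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 0:
        return 0, res.x[:N], res.x[N]
    if res.status == 2:
        return 2, None, None
    raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")


def is_realizable(
    cb: Codebook | np.ndarray,
    fa: FieldArrangement | Sequence[int],
    nonneg: bool = False,
) -> bool:
    """Is this labeling linearly separable with a free threshold?

    Solves the unit-gap feasibility LP over ``(w, theta)``; with
    ``nonneg=True`` the weights are constrained to be non-negative (the
    threshold stays free).  All-zero and all-one labelings are realizable
    (``w = 0`` with an appropriate threshold).

    Raises
    ------
    RuntimeError
        If the solver fails for a reason other than infeasibility.
    """
    X = _as_matrix(cb)
    y = _as_labels(fa)
    if y.size != X.shape[1]:
        raise ValueError("label length does not match pattern count")
    if y.all() or not y.any():
        return True
    status, _, _ = _unit_gap_lp(X, y, nonneg, minimize_l1=False)
    return status == 0


def max_margin(
    cb: Codebook | np.ndarray, fa: FieldArrangement | Sequence[int]
) -> PerceptronSolution:
    """Maximum-margin separator (hard-margin SVM, free threshold).

    The reported ``margin`` sums the two per-class boundary distances; at
    the symmetric optimum it equals ``2 / ||w||``.  An infeasible labeling
    returns ``feasible=False`` rather than raising, so margin experiments
    can skip unrealizable arrangements gracefully.
    """
    X = _as_matrix(cb)
    y = _as_labels(fa)
    if y.all() or not y.any():
        return PerceptronSolution(
            weights=np.zeros(X.shape[0]),
            threshold=-1.0 if y.all() else 1.0,
            feasible=True,
            margin=0.0,
            solver_status="single_class",
        )
    for C in (_HARD_C, 1e13):
        clf = SVC(kernel="linear", C=C, max_iter=200_000)
        with warnings.catch_warnings():
            # non-convergence at huge C is handled by the LP fallback below
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X.T, y)
        w = clf.coef_.ravel()
        theta = -float(clf.intercept_[0])
        scores = X.T @ w - theta
        if bool(np.all((scores > 0) == (y == 1))):
            norm = float(np.linalg.norm(w))
            half = 1.0 / norm
            return PerceptronSolution(
                weights=w,
                threshold=theta,
                feasible=True,
                margin=2.0 * half,
                geometric_margin=half,
                solver_status="optimal",
            )
    # SVC could not strictly separate: decide feasibility by the LP.  For
    # near-degenerate (tiny-margin) realizable labelings, the L1-minimizing
    # unit-gap separator gives a valid margin lower bound.
    status, w, theta = _unit_gap_lp(X, y, nonneg=False, minimize_l1=True)
    if status != 0:
        return PerceptronSolution(
            weights=None, threshold=None, feasible=False, margin=0.0,
            solver_status="not_realizable",
        )
    norm = float(np.linalg.norm(w))
    half = 1.0 / norm
    return PerceptronSolution(
        weights=w,
        threshold=float(theta),
        feasible=True,
        margin=2.0 * half,
        geometric_margin=half,
        solver_status="lp_lower_bound",
    )


def _iter_labelings(P: int, K: int | str) -> Iterable[np.ndarray]:
    if K == "all":
        for bits in itertools.product((0, 1), repeat=P):
            yield np.array(bits, dtype=np.int8)
    else:
        for idx in itertools.combinations(range(P), int(K)):
            y = np.zeros(P, dtype=np.int8)
            y[list(idx)] = 1
            yield y


def count_realizable(
    cb: Codebook | np.ndarray, K: int | str = "all", nonneg: bool = False
) -> int:
    """Exact count of realizable labelings by exhaustive enumeration.

    ``K="all"`` counts every labeling including the empty and full ones;
    an integer ``K`` restricts to labelings with exactly K fields.
    """
    return sum(1 for _ in enumerate_realizable(cb, K, nonneg))


def enumerate_realizable(
    cb: Codebook | np.ndarray, K: int | str = "all", nonneg: bool = False
) -> Iterable[FieldArrangement]:
    """Yield every realizable labeling (exhaustive, under the cap)."""
    X = _as_matrix(cb)
    P = X.shape[1]
    import math as _math

    total = 2**P if K == "all" else _math.comb(P, int(K))
    if total > ENUMERATION_CAP:
        raise ValueError(
            f"{total} labelings exceed the enumeration cap {ENUMERATION_CAP}; "
            "use closed-form counts or the lonesum path"
        )
    for y in _iter_labelings(P, K):
        if is_realizable(X, y, nonneg=nonneg):
            yield FieldArrangement(y)


def labels_to_module_grid(
    labels: Sequence[int], lam1: int, lam2: int
) -> np.ndarray:
    """Arrange full-range labels on the module-phase grid (lam1 x lam2).

    Location ``j`` maps to phase pair ``(j % lam1, j % lam2)``; requires the
    labeling to cover the full range ``LCM(lam1, lam2)``.  Cells of the grid
    not visited by any location (non-coprime periods) are left 0.
    """
    labels = np.asarray(labels, dtype=np.int8)
    grid = np.zeros((lam1, lam2), dtype=np.int8)
    for j, lab in enumerate(labels):
        grid[j % lam1, j % lam2] = lab
    return grid


def is_lonesum(label_matrix: np.ndarray) -> bool:
    """Does this binary matrix avoid both 2x2 permutation submatrices?

    Equivalently: the row supports can be totally ordered by inclusion
    (a staircase / Young-diagram shape after sorting).  For two grid
    modules this characterizes exactly the realizable field arrangements.
    """
    A = np.asarray(label_matrix, dtype=bool)
    order = np.argsort(A.sum(axis=1))[::-1]
    A = A[order]
    for upper, lower in zip(A[:-1], A[1:]):
        if np.any(lower & ~upper):
            return False
    return True


def sample_realizable(
    cb: Codebook | np.ndarray,
    K: int,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    method: str = "weights",
    max_retries: int = 1000,
) -> list[FieldArrangement]:
    """Sample realizable K-field arrangements.

    ``method="weights"`` draws a random perceptron: weights i.i.d. uniform
    [0,1] with the threshold at the midpoint between the K-th and (K+1)-th
    largest weighted input sums, so the induced labeling has exactly K
    supra-threshold patterns and is realizable by construction (ties
    trigger a redraw).  This is how a place cell with random non-negative
    weights actually produces arrangements, and for grid codes it covers
    the realizable set well.

    ``method="uniform"`` draws K-subsets of patterns uniformly at random
    and keeps those that pass the LP feasibility test — unbiased over
    K-subsets, but expensive when the realizable fraction is small (each
    sample spends up to ``max_retries`` LP calls before failing).
    """
    X = _as_matrix(cb)
    N, P = X.shape
    if not (1 <= K <= P):
        raise ValueError(f"K={K} out of range 1..{P}")
    if method not in ("weights", "uniform"):
        raise ValueError(f"unknown sampling method {method!r}")
    rng = np.random.default_rng(seed)
    out: list[FieldArrangement] = []
    for s in range(n_samples):
        for attempt in range(max_retries):
            if method == "weights":
                w = rng.uniform(size=N)
                scores = w @ X
                order = np.sort(scores)[::-1]
                if K == P:
                    theta = order[-1] - 1.0
                else:
                    if order[K - 1] - order[K] <= 1e-12 * max(1.0, abs(order[K])):
                        continue  # tie: redraw
                    theta = 0.5 * (order[K - 1] + order[K])
                y = (scores > theta).astype(np.int8)
                if int(y.sum()) == K:
                    out.append(FieldArrangement(y))
                    break
            else:
                y = np.zeros(P, dtype=np.int8)
                y[rng.choice(P, size=K, replace=False)] = 1
                if is_realizable(X, y):
                    out.append(FieldArrangement(y))
                    break
        else:
            raise RuntimeError(
                f"failed to sample a realizable K={K} arrangement on a "
                f"{N}x{P} codebook after {max_retries} retries "
                f"(method={method!r})"
            )
    return out
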