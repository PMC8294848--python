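"""Input-code generators.

Every input code studied by the model is generated here: the binary periodic
grid code, the modular-one-hot generalization, one-hot and binary codes,
random real-valued codes, shuffled grid codes, graded (Gaussian phase-tuned)
grid responses, and quasi-periodic 1D responses obtained as slices through
2D hexagonal lattices.  All stochastic generators are deterministic under a
seed.

Conventions
-----------
Codebooks are stored as ``N x P`` matrices: rows are cells, columns are
input patterns.  For spatially embedded codes, column ``j`` is the
population response at (0-based) location ``j``.  In a grid code, cell ``i``
of a module with integer period ``lam`` is active at location ``j`` iff
``(j - i) % lam == 0``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ModuleSpec",
    "Codebook",
    "GradedTuningSpec",
    "NoiseSpec",
    "make_grid_codebook",
    "full_range",
    "make_modular_one_hot",
    "make_one_hot",
    "make_binary",
    "make_random",
    "shuffle_grid",
    "graded_tuning",
    "slice_2d_grid",
    "normalize_l1",
    "add_dense_noise",
    "add_sparse_inputs",
    "shift_operator",
    "make_grid_codebook_2d",
]

#: hard cap on enumerated pattern counts; exceeding it raises, never truncates
PATTERN_CAP = 2**20


@dataclass(frozen=True)
class ModuleSpec:
    """Architecture of the grid input: module periods and spatial layout.

    Parameters
    ----------
    periods
        Spatial periods ``lam_1..lam_M``, one per module, in units of
        spatial bins.  Integer periods give exactly periodic codes; real
        periods are handled through the resolution parameter ``q``.
    d
        Spatial dimension (1 or 2).
    q
        Phase-resolution parameter used when periods are real-valued.
    """

    periods: tuple[float, ...]
    d: int = 1
    q: int = 1

    def __post_init__(self):
        if len(self.periods) < 1:
            raise ValueError("need at least one module period")
        if any(p < 2 for p in self.periods):
            raise ValueError("module periods must be >= 2")
        if self.d not in (1, 2):
            raise ValueError("spatial dimension must be 1 or 2")
        if self.q < 1:
            raise ValueError("resolution parameter q must be >= 1")
        object.__setattr__(self, "periods", tuple(self.periods))

    @property
    def M(self) -> int:
        return len(self.periods)

    @property
    def integer(self) -> bool:
        return all(float(p).is_integer() for p in self.periods)

    def int_periods(self) -> tuple[int, ...]:
        if not self.integer:
            raise ValueError(
                "periods are not integers; use graded_tuning or the "
                "resolution-q rank path for real-valued periods"
            )
        return tuple(int(p) for p in self.periods)


@dataclass
class Codebook:
    """A set of input patterns with optional module structure.

    ``patterns`` is ``N x P`` (cells x patterns).  ``module_of_cell`` maps
    each row to its module index, or ``-1`` for non-modular codes.
    ``locations`` gives the spatial coordinate of each column when the code
    is spatially embedded.
    """

    patterns: np.ndarray
    kind: str
    module_of_cell: np.ndarray | None = None
    locations: np.ndarray | None = None
    periods: tuple[float, ...] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    def column_set(self) -> set[tuple]:
        return {tuple(col) for col in self.patterns.T.tolist()}

    def to_csv(self, path: str | Path) -> None:
        """Write patterns as CSV (rows = cells, columns = locations)."""
        np.savetxt(path, self.patterns, delimiter=",", fmt="%.10g")

    def meta_json(self) -> str:
        payload = {
            "kind": self.kind,
            "n_cells": int(self.n_cells),
            "n_patterns": int(self.n_patterns),
            "periods": list(self.periods) if self.periods else None,
        }
        payload.update({k: v for k, v in self.meta.items() if _jsonable(v)})
        return json.dumps(payload)


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# grid and modular-one-hot codes


def full_range(spec: ModuleSpec | Sequence[int]) -> int:
    """Number of locations before the multi-module grid code repeats.

    Equals ``LCM(lam_1, ..., lam_M)`` for integer periods.
    """
    periods = spec.int_periods() if isinstance(spec, ModuleSpec) else [int(p) for p in spec]
    if not periods:
        raise ValueError("empty period list")
    return math.lcm(*periods)


def make_grid_codebook(
    spec: ModuleSpec | Sequence[int], range_len: int | str = "full"
) -> Codebook:
    """Binary periodic grid codebook over contiguous 1D locations.

    Cell ``i`` of module ``m`` (0-based within the module) is active at
    location ``j`` iff ``(j - i) % lam_m == 0``; each module therefore has
    exactly one active cell per location, and the code repeats after
    ``LCM(periods)`` locations.
    """
    if not isinstance(spec, ModuleSpec):
        spec = ModuleSpec(tuple(float(p) for p in spec))
    periods = spec.int_periods()
    L = full_range(periods)
    if range_len == "full":
        P = L
    else:
        P = int(range_len)
        if P < 1 or P > L:
            raise ValueError(f"range_len must be in 1..{L}")
    N = sum(periods)
    if P > PATTERN_CAP:
        raise ValueError(f"pattern count {P} exceeds cap {PATTERN_CAP}")
    X = np.zeros((N, P), dtype=np.int8)
    module_of_cell = np.empty(N, dtype=np.intp)
    row = 0
    j = np.arange(P)
    for m, lam in enumerate(periods):
        for i in range(lam):
            X[row + i] = ((j - i) % lam == 0).astype(np.int8)
        module_of_cell[row : row + lam] = m
        row += lam
    return Codebook(
        patterns=X,
        kind="grid",
        module_of_cell=module_of_cell,
        locations=np.arange(P),
        periods=tuple(float(p) for p in periods),
        meta={"L": L},
    )


def shift_operator(spec: ModuleSpec | Sequence[int]) -> np.ndarray:
    """Block-diagonal cyclic permutation J advancing the grid code one bin.

    Satisfies ``x_{j+1} = J @ x_j`` for columns of :func:`make_grid_codebook`.
    """
    if not isinstance(spec, ModuleSpec):
        spec = ModuleSpec(tuple(float(p) for p in spec))
    periods = spec.int_periods()
    N = sum(periods)
    J = np.zeros((N, N), dtype=np.int8)
    row = 0
    for lam in periods:
        for i in range(lam):
            J[row + (i + 1) % lam, row + i] = 1
        row += lam
    return J


def make_modular_one_hot(spec: ModuleSpec | Sequence[int]) -> Codebook:
    """All cross-module one-hot combinations: ``prod(lam_m)`` patterns.

    For pairwise-coprime periods this coincides, as a pattern set, with the
    full-range grid codebook; otherwise it is a strict superset.
    """
    if not isinstance(spec, ModuleSpec):
        spec = ModuleSpec(tuple(float(p) for p in spec))
    periods = spec.int_periods()
    P = math.prod(periods)
    if P > PATTERN_CAP:
        raise ValueError(f"pattern count {P} exceeds cap {PATTERN_CAP}")
    N = sum(periods)
    X = np.zeros((N, P), dtype=np.int8)
    module_of_cell = np.concatenate(
        [np.full(lam, m, dtype=np.intp) for m, lam in enumerate(periods)]
    )
    offsets = np.cumsum([0] + list(periods[:-1]))
    for col, combo in enumerate(itertools.product(*(range(lam) for lam in periods))):
        for off, i in zip(offsets, combo):
            X[off + i, col] = 1
    return Codebook(
        patterns=X,
        kind="modular_one_hot",
        module_of_cell=module_of_cell,
        periods=tuple(float(p) for p in periods),
    )


def make_one_hot(n: int) -> Codebook:
    """One-hot code: n cells, n patterns, each a standard basis vector."""
    if n < 1:
        raise ValueError("need n >= 1 cells")
    return Codebook(patterns=np.eye(n, dtype=np.int8), kind="one_hot")


def make_binary(n: int, cap: int = 20) -> Codebook:
    """All 2^n binary activity patterns of n cells (columns in counting order)."""
    if n > cap:
        raise ValueError(f"n={n} exceeds enumeration cap {cap}")
    cols = np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.int8).T
    return Codebook(patterns=cols, kind="binary")


def make_random(n: int, p: int, seed: int | np.random.Generator = 0) -> Codebook:
    """Random code: n x p matrix with i.i.d. uniform [0,1] entries."""
    rng = np.random.default_rng(seed)
    return Codebook(patterns=rng.uniform(size=(n, p)), kind="random", meta={"seed": seed})


def shuffle_grid(cb: Codebook, seed: int | np.random.Generator = 0) -> Codebook:
    """Per-pattern row shuffle of a grid codebook.

    Each column's entries are independently permuted across all rows, which
    destroys the modular structure while preserving each column's value
    multiset (and hence its L1 norm).
    """
    if cb.kind != "grid":
        raise ValueError("shuffle_grid expects a grid codebook")
    rng = np.random.default_rng(seed)
    X = cb.patterns.copy()
    for j in range(X.shape[1]):
        X[:, j] = X[rng.permutation(X.shape[0]), j]
    return Codebook(
        patterns=X, kind="shuffled", locations=cb.locations, periods=cb.periods,
        meta={"seed": seed},
    )


# ---------------------------------------------------------------------------
# graded tuning and 2D-lattice slices


@dataclass
class GradedTuningSpec:
    """Gaussian phase tuning for graded grid responses.

    The activation of a cell with preferred phase ``phi`` in a module whose
    phase at position x is ``phase_m(x) = (x / lam_m) mod 1`` is
    ``exp(-dist(phase_m, phi)^2 / (2 sigma_g^2))`` with the wrapped phase
    distance ``dist(a) = min(|a|, 1 - |a|)``.  The default width
    ``sigma_g = 0.16`` gives a tuning curve whose full width at half max is
    3/8 of the module period.
    """

    sigma_g: float = 0.16
    phases: list[np.ndarray] | None = None  # one array per module, in [0,1)
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.sigma_g < 0.5):
            raise ValueError("sigma_g must lie in (0, 0.5)")


def wrapped_phase_distance(a: np.ndarray | float) -> np.ndarray | float:
    """Distance on the phase circle: ``min(|a|, 1 - |a|)``."""
    a = np.abs(np.asarray(a, dtype=float)) % 1.0
    return np.minimum(a, 1.0 - a)


def graded_tuning(
    spec: ModuleSpec | Sequence[float],
    gspec: GradedTuningSpec,
    locations: Sequence[float],
) -> Codebook:
    """Graded grid responses: Gaussian bumps in module phase at each location.

    If ``gspec.phases`` is ``None``, preferred phases are drawn uniformly at
    random (``ceil(lam_m)`` cells per module) with ``gspec.seed``.
    """
    if not isinstance(spec, ModuleSpec):
        spec = ModuleSpec(tuple(float(p) for p in spec))
    x = np.asarray(locations, dtype=float)
    rng = np.random.default_rng(gspec.seed)
    phases = gspec.phases
    if phases is None:
        phases = [rng.uniform(size=math.ceil(lam)) for lam in spec.periods]
    rows, module_of_cell = [], []
    for m, lam in enumerate(spec.periods):
        phase_m = (x / lam) % 1.0
        for phi in phases[m]:
            d = wrapped_phase_distance(phase_m - phi)
            rows.append(np.exp(-(d**2) / (2.0 * gspec.sigma_g**2)))
            module_of_cell.append(m)
    return Codebook(
        patterns=np.vstack(rows),
        kind="graded",
        module_of_cell=np.array(module_of_cell, dtype=np.intp),
        locations=x,
        periods=spec.periods,
        meta={"sigma_g": gspec.sigma_g},
    )


def slice_2d_grid(
    period: float,
    n_cells: int,
    track_length: float,
    bin_size: float,
    gspec: GradedTuningSpec | None = None,
    seed: int | np.random.Generator = 0,
    angle: float | None = None,
) -> Codebook:
    """Quasi-periodic 1D grid responses as a slice through a 2D lattice.

    Each cell's 2D response is a sum of Gaussian bumps centered on the
    points of a hexagonal lattice (lattice vectors at 0 and 60 degrees,
    spacing ``period``, bump width ``sigma_g * period``), offset by a random
    2D phase per cell.  The 1D tuning curve samples this response along a
    straight line through the plane; unless given, the slice angle is drawn
    uniformly (seeded).  Rational vs irrational projections of the lattice
    vectors make the resulting 1D responses quasi-periodic rather than
    exactly periodic in general.
    """
    if period <= 0 or bin_size <= 0:
        raise ValueError("period and bin_size must be positive")
    gspec = gspec or GradedTuningSpec()
    rng = np.random.default_rng(seed)
    if angle is None:
        angle = rng.uniform(0.0, np.pi / 3.0)
    n_bins = int(round(track_length / bin_size))
    x = (np.arange(n_bins) + 0.5) * bin_size
    if n_bins == 0:
        return Codebook(
            patterns=np.zeros((n_cells, 0)), kind="slice2d",
            locations=np.zeros(0), periods=(period,),
        )
    # points along the slice, in lattice (oblique) coordinates
    pts = np.stack([x * np.cos(angle), x * np.sin(angle)], axis=1)
    A = period * np.array([[1.0, 0.5], [0.0, np.sqrt(3.0) / 2.0]])  # lattice basis
    Ainv = np.linalg.inv(A)
    sigma = gspec.sigma_g * period
    offsets = rng.uniform(size=(n_cells, 2))  # per-cell 2D phase, lattice coords
    # nearest-lattice-point distances via a 3x3 neighbor search in lattice coords
    neigh = np.array(list(itertools.product((-1, 0, 1), repeat=2)), dtype=float)
    X = np.empty((n_cells, n_bins))
    lat = pts @ Ainv.T  # (n_bins, 2) lattice coordinates of the slice points
    for c in range(n_cells):
        frac = lat - offsets[c]
        base = np.floor(frac)
        resp = np.zeros(n_bins)
        for nb in neigh:
            delta = (frac - base - nb) @ A.T
            resp += np.exp(-np.sum(delta**2, axis=1) / (2.0 * sigma**2))
        X[c] = resp
    return Codebook(
        patterns=X,
        kind="slice2d",
        module_of_cell=np.zeros(n_cells, dtype=np.intp),
        locations=x,
        periods=(period,),
        meta={"angle": float(angle), "sigma_g": gspec.sigma_g, "bin_size": bin_size},
    )


# ---------------------------------------------------------------------------
# normalization and nongrid inputs


def normalize_l1(cb: Codebook) -> Codebook:
    """Rescale every column (pattern) to unit L1 norm."""
    sums = np.abs(cb.patterns).sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"all-zero column(s) at indices {zero.tolist()}")
    out = Codebook(
        patterns=cb.patterns / sums,
        kind=cb.kind,
        module_of_cell=cb.module_of_cell,
        locations=cb.locations,
        periods=cb.periods,
        meta={**cb.meta, "l1_normalized": True},
    )
    return out


@dataclass
class NoiseSpec:
    """Nongrid input parameters.

    ``level`` is the mean of each added input relative to the grid
    population mean ``mu_g = M / N`` (for two modules, ``2/(lam1+lam2)``).
    Dense noise draws i.i.d. uniform values in ``[0, 2*level*mu_g]``; sparse
    cues are {0,1} rows with exactly ``Q = round(level * L * mu_g)`` ones.
    """

    n_extra: int = 100
    level: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.n_extra < 0:
            raise ValueError("n_extra must be >= 0")
        if self.level <= 0:
            raise ValueError("level must be positive")


def _grid_population_mean(cb: Codebook) -> float:
    if cb.periods is None:
        raise ValueError("codebook has no module periods")
    M = len(cb.periods)
    N = cb.n_cells
    return M / N


def add_dense_noise(cb: Codebook, nspec: NoiseSpec) -> Codebook:
    """Append dense noisy nongrid rows, then renormalize columns to unit L1.

    Each added entry is uniform in ``[0, 2 mu]`` with
    ``mu = level * mu_g``, so its expected value is ``level * mu_g``.
    """
    mu = nspec.level * _grid_population_mean(cb)
    rng = np.random.default_rng(nspec.seed)
    extra = rng.uniform(0.0, 2.0 * mu, size=(nspec.n_extra, cb.n_patterns))
    X = np.vstack([cb.patterns.astype(float), extra])
    out = Codebook(
        patterns=X,
        kind=cb.kind,
        locations=cb.locations,
        periods=cb.periods,
        meta={**cb.meta, "noise": "dense", "n_extra": nspec.n_extra, "level": nspec.level},
    )
    return normalize_l1(out)


def add_sparse_inputs(cb: Codebook, nspec: NoiseSpec) -> Codebook:
    """Append sparse {0,1} cue rows with Q ones each, then renormalize.

    ``Q = round(level * L * mu_g)`` ones per row at uniformly random
    locations across the full range.
    """
    L = cb.n_patterns
    Q = int(round(nspec.level * L * _grid_population_mean(cb)))
    if nspec.n_extra > 0 and Q < 1:
        raise ValueError(f"sparse-input density too low: Q={Q} < 1")
    rng = np.random.default_rng(nspec.seed)
    extra = np.zeros((nspec.n_extra, L))
    for r in range(nspec.n_extra):
        extra[r, rng.choice(L, size=Q, replace=False)] = 1.0
    X = np.vstack([cb.patterns.astype(float), extra])
    out = Codebook(
        patterns=X,
        kind=cb.kind,
        locations=cb.locations,
        periods=cb.periods,
        meta={**cb.meta, "noise": "sparse", "n_extra": nspec.n_extra, "Q": Q},
    )
    return normalize_l1(out)


# ---------------------------------------------------------------------------
# 2D grid code (square-lattice phase code used for d=2 rank/capacity checks)


def make_grid_codebook_2d(periods: Sequence[int]) -> Codebook:
    """2D grid code: module m has lam_m^2 cells one-hot coding its 2D phase.

    Locations range over the full 2D range ``LCM x LCM``; the cell with
    phase ``(i1, i2)`` in module m is active at ``(x, y)`` iff
    ``x % lam_m == i1`` and ``y % lam_m == i2``.
    """
    periods = [int(p) for p in periods]
    L = math.lcm(*periods)
    if L * L > PATTERN_CAP:
        raise ValueError("2D full range exceeds pattern cap")
    N = sum(p * p for p in periods)
    X = np.zeros((N, L * L), dtype=np.int8)
    module_of_cell = np.empty(N, dtype=np.intp)
    xs, ys = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    row = 0
    for m, lam in enumerate(periods):
        for i1 in range(lam):
            for i2 in range(lam):
                X[row] = ((xs % lam == i1) & (ys % lam == i2)).astype(np.int8)
                module_of_cell[row] = m
                row += 1
    locs = np.stack([xs, ys], axis=1)
    return Codebook(
        patterns=X,
        kind="grid2d",
        module_of_cell=module_of_cell,
        locations=locs,
        periods=tuple(float(p) for p in periods),
        meta={"L": L, "d": 2},
    )
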