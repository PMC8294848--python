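"""Hebbian field-insertion experiments on quasi-periodic grid inputs.

These experiments probe the stability of a place cell's field arrangement
when its grid-to-place weights are changed by Hebbian plasticity.  A
realizable K-field arrangement is built on graded, quasi-periodic inputs
(1D slices through 2D hexagonal lattices) over a long track; a new field is
then inserted at a chosen location by potentiating the weights in
proportion to the presynaptic activity there.  Because the grid inputs are
globally active and multi-periodic, this structured weight change perturbs
the summed input everywhere, and fields appear or disappear at remote,
uncontrolled locations — the volatility of the grid-driven scaffold.

Defaults model a rodent-scale experiment: a 20 m track at 5 cm bins with
two modules of periods 0.4 m and 0.6 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from gridplace.codebooks import Codebook, GradedTuningSpec, slice_2d_grid
from gridplace.separability import FieldArrangement, max_margin, sample_realizable

__all__ = [
    "PlasticitySpec",
    "VolatilityReport",
    "make_slice_inputs",
    "extract_fields",
    "build_arrangement",
    "hebbian_insert",
    "interval_change_histogram",
    "autocorrelation_alignment",
    "volatility_rate_experiment",
]


@dataclass
class PlasticitySpec:
    """Hebbian insertion rule.

    The weight update is ``w <- w + eta * x(target)`` with ``eta`` chosen as
    the smallest value that lifts the summed input at the target above
    threshold by ``clearance`` times its original deficit.
    """

    clearance: float = 0.05
    match_tol_bins: int = 3  # fields closer than this (bins) are "the same"

    def __post_init__(self):
        if self.clearance <= 0:
            raise ValueError("clearance must be positive")


@dataclass
class VolatilityReport:
    """Accounting of one field-insertion event."""

    target_bin: int
    fields_before: list[int]  # peak bins
    fields_after: list[int]
    persisting: list[tuple[int, int]]  # (before peak, after peak) matches
    insertions: list[int]  # off-target new field peaks
    deletions: list[int]  # lost original field peaks
    track_length: float
    bin_size: float

    @property
    def off_target_count(self) -> int:
        return len(self.insertions) + len(self.deletions)

    @property
    def rate_per_meter(self) -> float:
        return self.off_target_count / self.track_length

    def interval_deltas(self) -> np.ndarray:
        """Changes in pairwise inter-field intervals among persisting fields."""
        before = np.array([b for b, _ in self.persisting], dtype=float)
        after = np.array([a for _, a in self.persisting], dtype=float)
        deltas = []
        for i in range(len(before)):
            for j in range(i + 1, len(before)):
                deltas.append((after[i] - after[j]) - (before[i] - before[j]))
        return np.abs(np.asarray(deltas)) * self.bin_size


def make_slice_inputs(
    periods: Sequence[float] = (0.4, 0.6),
    track_length: float = 20.0,
    bin_size: float = 0.05,
    cells_per_module: Sequence[int] | None = None,
    sigma_g: float = 0.16,
    seed: int | np.random.Generator = 0,
) -> Codebook:
    """Quasi-periodic multi-module inputs over a 1D track.

    Each module's cells are parallel 1D slices through a 2D hexagonal
    lattice of Gaussian bumps (period in meters); by default a module of
    period ``lam`` gets ``round(lam / bin_size)`` cells, mirroring the
    one-cell-per-phase convention of the binary code.
    """
    rng = np.random.default_rng(seed)
    if cells_per_module is None:
        cells_per_module = [int(round(p / bin_size)) for p in periods]
    gspec = GradedTuningSpec(sigma_g=sigma_g)
    mats, module_of_cell = [], []
    for m, (lam, n_cells) in enumerate(zip(periods, cells_per_module)):
        cb = slice_2d_grid(
            period=lam, n_cells=n_cells, track_length=track_length,
            bin_size=bin_size, gspec=gspec, seed=rng,
        )
        mats.append(cb.patterns)
        module_of_cell.extend([m] * n_cells)
    X = np.vstack(mats)
    n_bins = X.shape[1]
    return Codebook(
        patterns=X,
        kind="slice2d",
        module_of_cell=np.array(module_of_cell, dtype=np.intp),
        locations=(np.arange(n_bins) + 0.5) * bin_size,
        periods=tuple(periods),
        meta={"track_length": track_length, "bin_size": bin_size},
    )


def extract_fields(scores: np.ndarray) -> list[int]:
    """Peak bins of contiguous supra-threshold runs of ``w.x - theta``."""
    above = scores > 0
    fields = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            seg = scores[start:i]
            fields.append(start + int(np.argmax(seg)))
            start = None
    if start is not None:
        seg = scores[start:]
        fields.append(start + int(np.argmax(seg)))
    return fields


def build_arrangement(
    inputs: Codebook,
    K: int,
    seed: int | np.random.Generator = 0,
    min_separation: int = 6,
    max_retries: int = 200,
):
    """A realizable K-field arrangement and its max-margin read-out.

    Draws a random-weight perceptron (weights i.i.d. uniform [0,1]) and
    places the threshold between the K-th and (K+1)-th tallest local maxima
    of the summed input, so exactly K contiguous supra-threshold runs
    (fields) emerge; the arrangement is realizable by construction.  The
    returned solution is the hard-margin separator for that bin labeling,
    and is accepted only if its fields are pairwise separated by at least
    ``min_separation`` bins and still number K.
    """
    rng = np.random.default_rng(seed)
    X = inputs.patterns
    for _ in range(max_retries):
        w = rng.uniform(size=X.shape[0])
        s = w @ X
        interior = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
        peaks = np.sort(s[1:-1][interior])[::-1]
        if peaks.size <= K:
            continue
        if peaks[K - 1] - peaks[K] <= 1e-12:
            continue
        theta = 0.5 * (peaks[K - 1] + peaks[K])
        labels = (s > theta).astype(np.int8)
        fields = extract_fields(s - theta)
        if len(fields) != K:
            continue
        if K > 1 and np.min(np.diff(np.sort(fields))) < min_separation:
            continue
        fa = FieldArrangement(labels)
        sol = max_margin(inputs, fa)
        if not sol.feasible:
            continue
        scores = sol.weights @ X - sol.threshold
        if len(extract_fields(scores)) == K:
            return sol, fa
    raise RuntimeError(f"no well-separated realizable K={K} arrangement found")


def hebbian_insert(
    sol,
    inputs: Codebook,
    target_bin: int,
    pspec: PlasticitySpec | None = None,
):
    """Insert a field at ``target_bin`` by Hebbian weight potentiation.

    Returns the updated solution (same threshold, potentiated weights) and
    a :class:`VolatilityReport` comparing the field sets before and after.
    """
    pspec = pspec or PlasticitySpec()
    X = inputs.patterns
    x_t = X[:, target_bin]
    xx = float(x_t @ x_t)
    if xx <= 0:
        raise ValueError(f"zero input at target bin {target_bin}")
    w, theta = sol.weights, sol.threshold
    scores = w @ X - theta
    before = extract_fields(scores)
    deficit = theta - float(w @ x_t)
    if deficit <= 0:
        raise ValueError("target is already a field")
    eta = (1.0 + pspec.clearance) * deficit / xx
    w_new = w + eta * x_t
    scores_new = w_new @ X - theta
    after = extract_fields(scores_new)
    tol = pspec.match_tol_bins
    persisting, deletions = [], []
    unmatched_after = list(after)
    for b in before:
        cand = [a for a in unmatched_after if abs(a - b) <= tol]
        if cand:
            a = min(cand, key=lambda a: abs(a - b))
            persisting.append((b, a))
            unmatched_after.remove(a)
        else:
            deletions.append(b)
    insertions = [a for a in unmatched_after if abs(a - target_bin) > tol]
    bin_size = float(inputs.meta.get("bin_size", 1.0))
    track = float(inputs.meta.get("track_length", X.shape[1] * bin_size))
    report = VolatilityReport(
        target_bin=target_bin,
        fields_before=before,
        fields_after=after,
        persisting=persisting,
        insertions=insertions,
        deletions=deletions,
        track_length=track,
        bin_size=bin_size,
    )
    new_sol = type(sol)(
        weights=w_new, threshold=theta, feasible=True,
        solver_status="hebbian_insert",
    )
    return new_sol, report


def interval_change_histogram(
    reports: Sequence[VolatilityReport], bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled histogram of |pairwise inter-field interval changes| (meters).

    Only persisting field pairs contribute; appeared and disappeared fields
    are bookkept separately in the reports.
    """
    deltas = [r.interval_deltas() for r in reports]
    pooled = np.concatenate(deltas) if deltas else np.zeros(0)
    if pooled.size == 0:
        return np.zeros(bins), np.linspace(0, 1, bins + 1)
    return np.histogram(pooled, bins=bins)


def autocorrelation_alignment(
    inputs: Codebook,
    weights: np.ndarray,
    reports: Sequence[VolatilityReport],
    n_surrogates: int = 200,
    seed: int = 0,
) -> dict:
    """Do new fields appear at input-autocorrelation peak spacings?

    Computes the autocorrelation of the weighted summed input, finds its
    peak lags, and scores the fraction of new-field spacings (distance from
    each inserted field to the nearest original field) that fall within a
    half-peak-width of a peak.  The same score on uniformly shuffled
    surrogate spacings gives the chance level.
    """
    g = weights @ inputs.patterns
    g = g - g.mean()
    ac = np.correlate(g, g, mode="full")[g.size - 1 :]
    ac /= ac[0]
    peaks, _ = find_peaks(ac)
    if peaks.size == 0:
        return {"score": np.nan, "surrogate_mean": np.nan, "peaks": peaks, "autocorr": ac}
    half_width = max(1, int(round(np.median(np.diff(peaks)) / 4))) if peaks.size > 1 else 2
    spacings = []
    for r in reports:
        for a in r.insertions:
            if r.fields_before:
                spacings.append(min(abs(a - b) for b in r.fields_before))
    spacings = np.asarray(spacings)
    if spacings.size == 0:
        return {"score": np.nan, "surrogate_mean": np.nan, "peaks": peaks, "autocorr": ac}

    def _score(sp):
        return float(np.mean([np.min(np.abs(peaks - s)) <= half_width for s in sp]))

    score = _score(spacings)
    rng = np.random.default_rng(seed)
    max_lag = ac.size - 1
    surr = [
        _score(rng.integers(1, max_lag, size=spacings.size))
        for _ in range(n_surrogates)
    ]
    return {
        "score": score,
        "surrogate_mean": float(np.mean(surr)),
        "spacings": spacings,
        "peaks": peaks,
        "half_width": half_width,
        "autocorr": ac,
    }


def volatility_rate_experiment(
    n_insertions_list: Sequence[int] = (1, 2, 3, 4),
    K: int = 8,
    periods: Sequence[float] = (0.4, 0.6),
    track_length: float = 20.0,
    bin_size: float = 0.05,
    cells_per_module: Sequence[int] | None = None,
    n_trials: int = 50,
    seed: int = 0,
    pspec: PlasticitySpec | None = None,
) -> dict[int, float]:
    """Mean off-target insertion+deletion rate (per meter) vs fields inserted.

    Each trial draws fresh quasi-periodic inputs and a fresh K-field
    arrangement, then inserts ``n`` fields sequentially at random non-field
    locations; off-target changes are counted against the *original* field
    set.  Zero insertions give zero rate by construction.
    """
    pspec = pspec or PlasticitySpec()
    rng = np.random.default_rng(seed)
    rates: dict[int, list[float]] = {n: [] for n in n_insertions_list}
    for trial in range(n_trials):
        inputs = make_slice_inputs(
            periods=periods, track_length=track_length, bin_size=bin_size,
            cells_per_module=cells_per_module, seed=rng,
        )
        try:
            sol0, fa0 = build_arrangement(inputs, K, rng)
        except RuntimeError:
            continue
        scores0 = sol0.weights @ inputs.patterns - sol0.threshold
        original = extract_fields(scores0)
        n_bins = inputs.n_patterns
        for n_ins in n_insertions_list:
            if n_ins == 0:
                rates[0].append(0.0)
                continue
            sol = sol0
            ok = True
            targets: list[int] = []
            for _ in range(n_ins):
                scores = sol.weights @ inputs.patterns - sol.threshold
                sub = np.flatnonzero(scores <= 0)
                far = sub[
                    np.array(
                        [min(abs(s - f) for f in original) > pspec.match_tol_bins for s in sub]
                    )
                ]
                if far.size == 0:
                    ok = False
                    break
                target = int(rng.choice(far))
                try:
                    sol, _ = hebbian_insert(sol, inputs, target, pspec)
                    targets.append(target)
                except ValueError:
                    ok = False
                    break
            if not ok:
                continue
            # compare final field set against the original one
            final = extract_fields(sol.weights @ inputs.patterns - sol.threshold)
            tol = pspec.match_tol_bins
            matched_after: set[int] = set()
            deletions = 0
            for b in original:
                cand = [a for a in final if abs(a - b) <= tol and a not in matched_after]
                if cand:
                    matched_after.add(min(cand, key=lambda a: abs(a - b)))
                else:
                    deletions += 1
            # fields near a deliberate target are controlled, not off-target
            insertions = sum(
                1
                for a in final
                if a not in matched_after
                and min(abs(a - b) for b in original) > tol
                and min(abs(a - t) for t in targets) > tol
            )
            rates[n_ins].append((insertions + deletions) / track_length)
    return {n: float(np.mean(v)) if v else np.nan for n, v in rates.items()}
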