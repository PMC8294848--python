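"""Codebook generators: patterns, invariants, noise augmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridplace.codebooks import (
    GradedTuningSpec,
    ModuleSpec,
    NoiseSpec,
    add_dense_noise,
    add_sparse_inputs,
    full_range,
    graded_tuning,
    make_binary,
    make_grid_codebook,
    make_grid_codebook_2d,
    make_modular_one_hot,
    make_one_hot,
    make_random,
    normalize_l1,
    shift_operator,
    shuffle_grid,
    slice_2d_grid,
    wrapped_phase_distance,
)

SIX_STATES = {"10100", "10010", "10001", "01100", "01010", "01001"}


def _column_strings(cb):
    return {"".join(str(int(v)) for v in col) for col in cb.patterns.T}


class TestGridCodebook:
    def test_periods_2_3_matches_printed_states(self, grid23):
        assert grid23.n_patterns == 6
        assert _column_strings(grid23) == SIX_STATES

    def test_one_active_cell_per_module_per_column(self):
        for periods in ([2, 3], [3, 4], [4, 6], [2, 3, 5]):
            cb = make_grid_codebook(periods)
            for m in range(len(periods)):
                rows = cb.patterns[cb.module_of_cell == m]
                assert np.all(rows.sum(axis=0) == 1)

    def test_single_module_is_identity(self):
        cb = make_grid_codebook([2])
        assert np.array_equal(cb.patterns, np.eye(2, dtype=np.int8))

    @pytest.mark.parametrize(
        "periods,expected", [([2, 3], 6), ([31, 43], 1333), ([4], 4), ([3, 4], 12)]
    )
    def test_full_range_is_lcm(self, periods, expected):
        assert full_range(periods) == expected

    def test_full_range_rejects_empty(self):
        with pytest.raises(ValueError):
            full_range([])

    def test_non_integer_periods_rejected_with_pointer(self):
        with pytest.raises(ValueError, match="graded"):
            make_grid_codebook(ModuleSpec((2.5, 3.0)))

    def test_translation_by_shift_operator(self, grid34):
        J = shift_operator([3, 4])
        X = grid34.patterns
        for j in range(X.shape[1]):
            assert np.array_equal(J @ X[:, j], X[:, (j + 1) % X.shape[1]])

    def test_circulant_convolution_preserves_rank(self, grid34):
        # graded tuning = convolution with a full-rank circulant kernel
        from scipy.linalg import circulant

        L = grid34.n_patterns
        lag = np.minimum(np.arange(L), L - np.arange(L))
        C = circulant(np.exp(-(lag**2) / (2 * 1.5**2)))
        assert np.linalg.matrix_rank(C) == L
        raw = np.linalg.matrix_rank(grid34.patterns.astype(float))
        conv = np.linalg.matrix_rank(grid34.patterns.astype(float) @ C)
        assert conv == raw == 6


class TestAlternativeCodes:
    def test_modular_one_hot_equals_grid_for_coprime(self):
        for periods in ([2, 3], [3, 4], [3, 5]):
            mo = make_modular_one_hot(periods)
            g = make_grid_codebook(periods)
            assert mo.n_patterns == math.prod(periods)
            assert mo.column_set() == g.column_set()

    def test_modular_one_hot_superset_for_non_coprime(self):
        mo = make_modular_one_hot([2, 4])
        g = make_grid_codebook([2, 4])
        assert mo.n_patterns == 8 and g.n_patterns == 4
        assert g.column_set() < mo.column_set()

    def test_modular_one_hot_2_2(self):
        assert make_modular_one_hot([2, 2]).n_patterns == 4

    def test_one_hot_is_identity(self):
        cb = make_one_hot(5)
        assert cb.n_patterns == 5
        assert np.all(cb.patterns.sum(axis=0) == 1)
        assert np.array_equal(cb.patterns, np.eye(5, dtype=np.int8))

    def test_binary_enumerates_hypercube(self):
        cb = make_binary(3)
        assert cb.n_patterns == 8
        assert len(cb.column_set()) == 8
        with pytest.raises(ValueError):
            make_binary(25)

    def test_random_deterministic_and_full_rank(self):
        a = make_random(5, 5, seed=7).patterns
        b = make_random(5, 5, seed=7).patterns
        assert np.array_equal(a, b)
        assert np.linalg.matrix_rank(a) == 5


class TestShuffle:
    def test_column_sums_preserved_and_deterministic(self, grid23):
        s = shuffle_grid(grid23, seed=3)
        assert np.array_equal(
            s.patterns.sum(axis=0), grid23.patterns.sum(axis=0)
        )
        assert np.array_equal(s.patterns, shuffle_grid(grid23, seed=3).patterns)

    def test_breaks_modular_structure(self, grid23):
        # over many seeds, at least one column must violate one-per-module
        violated = False
        for seed in range(100):
            s = shuffle_grid(grid23, seed=seed)
            top = s.patterns[:2].sum(axis=0)  # rows of former module 0
            if np.any(top != 1):
                violated = True
                break
        assert violated


class TestGradedTuning:
    def test_peak_activation_at_preferred_phase(self):
        gspec = GradedTuningSpec(phases=[np.array([0.25])])
        cb = graded_tuning(ModuleSpec((4.0,)), gspec, locations=[1.0])
        assert cb.patterns[0, 0] == pytest.approx(1.0)

    def test_fwhm_is_three_eighths_of_period(self):
        # measure the half-max width of an actual tuning curve
        lam = 4.0
        x = np.linspace(0.0, lam, 20001)
        gspec = GradedTuningSpec(phases=[np.array([0.5])])
        cb = graded_tuning(ModuleSpec((lam,)), gspec, x)
        curve = cb.patterns[0]
        above = x[curve >= 0.5]
        fwhm = above.max() - above.min()
        assert fwhm / lam == pytest.approx(3.0 / 8.0, rel=0.01)

    def test_wrapped_distance(self):
        assert wrapped_phase_distance(0.9 - 0.1) == pytest.approx(0.2)
        assert wrapped_phase_distance(-0.3) == pytest.approx(0.3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-5, 5, allow_nan=False))
    def test_wrapped_distance_bounds(self, a):
        d = wrapped_phase_distance(a)
        assert 0 <= d <= 0.5


class TestSlice2D:
    def test_zero_length_track_is_empty(self):
        cb = slice_2d_grid(0.5, 3, track_length=0.0, bin_size=0.05)
        assert cb.n_patterns == 0

    def test_deterministic_under_seed(self):
        a = slice_2d_grid(0.5, 4, 5.0, 0.05, seed=9).patterns
        b = slice_2d_grid(0.5, 4, 5.0, 0.05, seed=9).patterns
        assert np.array_equal(a, b)

    def test_same_module_cells_have_similar_mean_rates(self):
        cb = slice_2d_grid(0.5, 6, 60.0, 0.05, seed=2)
        means = cb.patterns.mean(axis=1)
        # phases differ but long-track averages agree up to edge effects
        assert means.std() / means.mean() < 0.2

    def test_quasi_periodic_autocorrelation_has_off_origin_peaks(self):
        from scipy.signal import find_peaks

        cb = slice_2d_grid(0.5, 8, 40.0, 0.05, seed=4)
        g = cb.patterns.sum(axis=0)
        g = g - g.mean()
        ac = np.correlate(g, g, "full")[g.size - 1 :]
        peaks, _ = find_peaks(ac, height=0.1 * ac[0])
        assert ac.argmax() == 0
        assert peaks.size >= 1


class TestNormalizationAndNoise:
    def test_l1_normalization_and_idempotence(self, grid23):
        n1 = normalize_l1(grid23)
        assert np.allclose(n1.patterns.sum(axis=0), 1.0)
        assert np.allclose(n1.patterns[n1.patterns > 0], 0.5)
        n2 = normalize_l1(n1)
        assert np.allclose(n1.patterns, n2.patterns)

    def test_all_zero_column_reported(self):
        from gridplace.codebooks import Codebook

        cb = Codebook(patterns=np.array([[1.0, 0.0], [0.0, 0.0]]), kind="grid")
        with pytest.raises(ValueError, match="1"):
            normalize_l1(cb)

    def test_dense_noise_level_and_normalization(self):
        cb = make_grid_codebook([31, 43])
        nspec = NoiseSpec(n_extra=100, seed=0)
        out = add_dense_noise(cb, nspec)
        assert out.n_cells == 74 + 100
        assert np.allclose(out.patterns.sum(axis=0), 1.0)
        # before renormalization the added entries average 0.2 * mu_g
        mu_g = 2 / 74
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 2 * 0.2 * mu_g, size=(100, 1333))
        assert raw.mean() == pytest.approx(0.2 * mu_g, rel=0.02)
        # summed noise ~ (0.2*100/74) x summed grid input (which is 2)
        assert raw.sum(axis=0).mean() == pytest.approx(0.2 * 100 / 74 * 2, rel=0.05)

    def test_zero_extra_inputs_leave_patterns_unchanged(self, grid23):
        out = add_dense_noise(grid23, NoiseSpec(n_extra=0, seed=1))
        assert np.allclose(out.patterns, normalize_l1(grid23).patterns)

    def test_sparse_inputs_have_exactly_Q_ones(self):
        cb = make_grid_codebook([31, 43])
        out = add_sparse_inputs(cb, NoiseSpec(n_extra=20, seed=5))
        Q = int(round(0.2 * 1333 * 2 / 74))
        assert Q == 7
        extra = out.patterns[74:] > 0
        assert np.all(extra.sum(axis=1) == Q)
        assert np.allclose(out.patterns.sum(axis=0), 1.0)


class TestGrid2D:
    def test_cells_and_one_hot_phase_structure(self):
        cb = make_grid_codebook_2d([2, 3])
        assert cb.n_cells == 4 + 9
        assert cb.n_patterns == 36
        for m, lam in enumerate([2, 3]):
            rows = cb.patterns[cb.module_of_cell == m]
            assert np.all(rows.sum(axis=0) == 1)
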