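"""Similarity statistic, analysis window, and cohort fingerprints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import strainprint as sp
from strainprint.errors import AlignmentError, ConfigurationError
from strainprint.fingerprint import AnalysisWindow


def brute_force_rms(p, i, window):
    """Independent oracle: literal sum-and-divide RMS over the window."""
    total = 0.0
    n = 0
    for k in range(window.start_index, window.end_index + 1):
        total += (p[k] - i[k]) ** 2
        n += 1
    return math.sqrt(total / n)


class TestSimilarity:
    def test_identity_is_zero(self):
        w = AnalysisWindow(0, 4)
        x = np.linspace(-0.1, 0.05, 5)
        assert sp.similarity(x, x, w) == 0.0

    def test_hand_computed_value(self):
        # single 0.06 deviation over three samples: sqrt(0.0036 / 3)
        w = AnalysisWindow(0, 2)
        p = np.array([0.0, 0.0, 0.0])
        i = np.array([0.06, 0.0, 0.0])
        assert sp.similarity(p, i, w) == pytest.approx(0.034641016151377546, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        w = AnalysisWindow(0, 19)
        p, i = rng.normal(0, 0.05, (2, 20))
        assert sp.similarity(p, i, w) == sp.similarity(i, p, w)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        w = AnalysisWindow(0, n - 1)
        p, i = rng.normal(0, 0.05, (2, n))
        assert sp.similarity(p, i, w) == pytest.approx(
            brute_force_rms(p, i, w), abs=1e-12
        )

    def test_mismatched_lengths_rejected(self):
        w = AnalysisWindow(0, 2)
        with pytest.raises(AlignmentError):
            sp.similarity(np.zeros(5), np.zeros(6), w)

    def test_window_beyond_arrays_rejected(self):
        w = AnalysisWindow(0, 10)
        with pytest.raises(AlignmentError):
            sp.similarity(np.zeros(5), np.zeros(5), w)


class TestAnalysisWindow:
    def test_two_thirds_of_systole_floored(self, waveform):
        # t_mvc=0, t_mvo=350: 2/3 of systole ends at 233.33 ms -> sample 232 ms
        w = sp.analysis_window(waveform)
        assert w.start_index == 0
        assert w.end_index == 116
        assert w.n == 117

    def test_on_grid_endpoint_exact(self):
        cfg = sp.ModelConfig(t_mvo=300.0)
        w = sp.analysis_window(sp.generate_external_tension(cfg))
        assert w.end_index == 100  # 200 ms on the 2 ms grid
        assert w.n == 101

    def test_degenerate_systole_rejected(self, waveform):
        bad = sp.TensionWaveform(
            t=waveform.t, G=waveform.G, t_mvc=350.0, t_mvo=350.0, t_onset=350.0
        )
        with pytest.raises(ConfigurationError):
            sp.analysis_window(bad)

    def test_too_short_window_rejected(self):
        with pytest.raises(ConfigurationError):
            AnalysisWindow(5, 5)


class TestBuildFingerprint:
    def test_library_row_contains_own_cell(self, library, window):
        i, j = 12, 25
        fp = sp.build_fingerprint(library.row(i, j), library, window)
        assert fp.mask[j, i]  # image axes are [con_index, at_index]

    def test_zero_threshold_marks_exact_matches_only(self, library, window):
        i, j = 20, 20
        fp = sp.build_fingerprint(library.row(i, j), library, window, threshold=0.0)
        assert fp.mask[j, i]
        # every marked cell is window-identical to the reference
        ref = library.row(i, j)[window.slice]
        for cj, ci in fp.points():
            assert np.array_equal(library.row(ci, cj)[window.slice], ref)

    def test_cohorts_nest_under_growing_threshold(self, library, window):
        rng = np.random.default_rng(7)
        for _ in range(10):
            i, j = rng.integers(0, 41, 2)
            small = sp.build_fingerprint(
                library.row(i, j), library, window, threshold=0.015
            )
            large = sp.build_fingerprint(
                library.row(i, j), library, window, threshold=0.03
            )
            assert np.all(large.mask[small.mask])

    def test_empty_cohort_warns_not_raises(self, library, window):
        far = np.full(library.traces.shape[1], 5.0)  # strain nowhere near model range
        with pytest.warns(UserWarning, match="empty cohort"):
            fp = sp.build_fingerprint(far, library, window)
        assert fp.is_empty

    def test_off_grid_reference_rejected(self, library, window):
        with pytest.raises(AlignmentError):
            sp.build_fingerprint(np.zeros(10), library, window)


class TestConnectedComponents:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ([(5, 5)], 1),
            ([(5, 5), (6, 6)], 1),      # diagonal touch joins under 8-connectivity
            ([(5, 5), (7, 7)], 2),
            ([], 0),
        ],
    )
    def test_counts(self, grid, cells, expected):
        mask = np.zeros((grid.n_con, grid.n_at), dtype=bool)
        for r, c in cells:
            mask[r, c] = True
        fp = sp.Fingerprint(mask=mask, grid=grid)
        count, labels = sp.connected_components(fp)
        assert count == expected
        assert labels.shape == mask.shape


class TestSyntheticFingerprints:
    def test_stack_shape_and_self_inclusion(self, synthetic_masks, grid):
        assert synthetic_masks.shape == (1681, grid.n_con, grid.n_at)
        for row in range(0, 1681, 97):
            i, j = grid.row_to_cell(row)
            assert synthetic_masks[row, j, i]

    def test_matches_per_trace_builder(self, synthetic_masks, library, window):
        i, j = 33, 8
        row = library.grid.cell_to_row(i, j)
        fp = sp.build_fingerprint(library.row(i, j), library, window)
        assert np.array_equal(synthetic_masks[row], fp.mask)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, similarity_matrix):
        assert similarity_matrix.shape == (1681, 1681)
        assert np.allclose(similarity_matrix, similarity_matrix.T, atol=1e-12)
        assert np.abs(np.diag(similarity_matrix)).max() < 1e-12
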