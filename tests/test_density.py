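"""Unit tests for density-map construction and the hotspot rule."""

import numpy as np
import pytest

from nengrade.density import (
    Detection,
    DensityMap,
    PatchGrid,
    hotspot,
    ki67_index_map,
    quantize_detections,
    sliding_sum,
    window_patches_for_area,
)
from nengrade.ki67 import CellCounts


def brute_force_window_sums(counts, window, mode):
    """Independent double-loop oracle for sliding_sum."""
    rows, cols = counts.shape
    half = window // 2
    if mode == "same":
        out = np.zeros_like(counts, dtype=float)
        for r in range(rows):
            for c in range(cols):
                r0, r1 = max(0, r - half), min(rows, r + half + 1)
                c0, c1 = max(0, c - half), min(cols, c + half + 1)
                out[r, c] = counts[r0:r1, c0:c1].sum()
    else:
        out = np.zeros((rows - window + 1, cols - window + 1))
        for r in range(out.shape[0]):
            for c in range(out.shape[1]):
                out[r, c] = counts[r : r + window, c : c + window].sum()
    return out


class TestWindowSize:
    @pytest.mark.parametrize(
        "area,mpp,patch,expected",
        [
            (2.0, 0.2525, 512, 11),  # the canonical 5632-px / 11-patch window
            (2.0, 0.2525, 1024, 5),
            (0.25, 1.0, 500, 1),  # sqrt(area)*1000 == mpp*patch exactly
        ],
    )
    def test_window_side(self, area, mpp, patch, expected):
        assert window_patches_for_area(area, mpp, patch) == expected

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            window_patches_for_area(0, 0.25, 512)
        with pytest.raises(ValueError):
            window_patches_for_area(2, -1, 512)


class TestQuantize:
    def test_no_detections_all_zero(self):
        counts = quantize_detections([], PatchGrid(4, 5))
        assert counts.shape == (4, 5) and counts.sum() == 0

    def test_origin_boundary_convention(self):
        counts = quantize_detections([Detection(0, 0, 1.0)], PatchGrid(3, 3), score_threshold=0.0)
        assert counts[0, 0] == 1 and counts.sum() == 1

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(8)
        grid = PatchGrid(6, 7, patch_size_px=128)
        dets = [
            Detection(rng.uniform(0, 7 * 128 + 50), rng.uniform(0, 6 * 128 + 50), rng.uniform())
            for _ in range(500)
        ]
        counts = quantize_detections(dets, grid, score_threshold=0.5)
        expected = sum(
            1 for d in dets if d.score >= 0.5 and d.x < 7 * 128 and d.y < 6 * 128
        )
        assert counts.sum() == expected

    def test_translation_equivariance(self):
        rng = np.random.default_rng(9)
        grid = PatchGrid(8, 8, patch_size_px=64)
        dets = [
            Detection(rng.uniform(0, 7 * 64), rng.uniform(0, 7 * 64), 1.0) for _ in range(200)
        ]
        shifted = [Detection(d.x + 64, d.y + 64, 1.0) for d in dets]
        a = quantize_detections(dets, grid, 0.0)
        b = quantize_detections(shifted, grid, 0.0)
        assert (a[:7, :7] == b[1:, 1:]).all()


class TestSlidingSum:
    def test_window_one_is_identity(self):
        counts = np.arange(12).reshape(3, 4)
        assert (sliding_sum(counts, 1).values == counts).all()

    def test_single_count_spreads_over_window(self):
        counts = np.zeros((31, 31))
        counts[15, 15] = 1
        values = sliding_sum(counts, 11).values
        assert (values == 1).sum() == 121
        assert values.sum() == 121

    def test_equals_brute_force_on_random_grids(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            counts = rng.poisson(0.5, size=(30, 40))
            got = sliding_sum(counts, 11, mode="same").values
            assert (got == brute_force_window_sums(counts, 11, "same")).all()
            got_v = sliding_sum(counts, 11, mode="valid").values
            assert (got_v == brute_force_window_sums(counts, 11, "valid")).all()

    def test_valid_equals_same_interior(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(1.0, size=(20, 25))
        same = sliding_sum(counts, 7, mode="same").values
        valid = sliding_sum(counts, 7, mode="valid").values
        assert (valid == same[3:-3, 3:-3]).all()

    def test_mask_gates_and_marks_missing(self):
        counts = np.ones((9, 9))
        mask = np.ones((9, 9), dtype=bool)
        mask[0, :] = False
        out = sliding_sum(counts, 3, mode="same", mask=mask).values
        assert np.isnan(out[0]).all()
        assert out[4, 4] == 9  # interior untouched by the masked row
        assert out[1, 4] == 6  # masked row contributed zero

    def test_even_window_same_mode_rejected(self):
        with pytest.raises(ValueError):
            sliding_sum(np.zeros((5, 5)), 4, mode="same")

    def test_oversized_window_valid_mode_rejected(self):
        with pytest.raises(ValueError):
            sliding_sum(np.zeros((5, 5)), 7, mode="valid")


class TestHotspot:
    def test_all_zero_map(self):
        value, row, col = hotspot(DensityMap(np.zeros((4, 4)), "mitotic_2mm2", 1))
        assert (value, row, col) == (0.0, 0, 0)

    def test_tie_breaks_row_major(self):
        values = np.zeros((3, 3))
        values[1, 2] = 5
        values[2, 0] = 5
        assert hotspot(DensityMap(values, "mitotic_2mm2", 1))[1:] == (1, 2)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            hotspot(DensityMap(np.full((3, 3), np.nan), "ki67_index", 1))

    def test_matches_brute_force_max_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            counts = rng.poisson(0.8, size=(rng.integers(12, 25), rng.integers(12, 25)))
            dmap = sliding_sum(counts, 5, mode="same")
            value, row, col = hotspot(dmap)
            oracle = brute_force_window_sums(counts, 5, "same")
            assert value == oracle.max()
            assert oracle[row, col] == value


class TestKi67Map:
    @staticmethod
    def _cells(index, qualifies=True):
        n_pos = 0 if np.isnan(index) else int(6 * index)
        return CellCounts(n_total=600, n_positive=n_pos, index_pct=index, qualifies=qualifies)

    def test_missing_exactly_at_unqualified(self):
        grid = PatchGrid(2, 2, patch_size_px=1536)
        per_patch = [
            (0, 0, self._cells(10.0)),
            (0, 1, self._cells(float("nan"), qualifies=False)),
            (1, 0, self._cells(25.0)),
            (1, 1, self._cells(0.0, qualifies=False)),
        ]
        dmap = ki67_index_map(per_patch, grid)
        assert dmap.values[0, 0] == 10.0 and dmap.values[1, 0] == 25.0
        assert np.isnan(dmap.values[0, 1]) and np.isnan(dmap.values[1, 1])

    def test_all_unqualified_gives_all_missing(self):
        grid = PatchGrid(1, 2, patch_size_px=1536)
        dmap = ki67_index_map(
            [(0, 0, self._cells(1, False)), (0, 1, self._cells(2, False))], grid
        )
        assert np.isnan(dmap.values).all()

    def test_duplicate_coordinates_rejected(self):
        grid = PatchGrid(2, 2, patch_size_px=1536)
        with pytest.raises(ValueError):
            ki67_index_map([(0, 0, self._cells(1)), (0, 0, self._cells(2))], grid)
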