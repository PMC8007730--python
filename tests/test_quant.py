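import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggrequant import (
    CellMaskSet,
    ThresholdParams,
    cell_intensity_stats,
    clustering_index,
    label_puncta,
    quantify_all_cells,
    quantify_cell,
    select_aggregate_pixels,
)
from conftest import brute_force_selection


class TestIntensityStats:
    def test_small_cell_mean_and_sample_sd(self, small_cell):
        img, mask = small_cell
        mean, sd, n = cell_intensity_stats(img, mask, 1)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(20))  # ~4.4721
        assert n == 5

    def test_constant_cell(self):
        img = np.full((2, 2), 7.0)
        mask = CellMaskSet(np.ones((2, 2), dtype=int))
        mean, sd, _ = cell_intensity_stats(img, mask, 1)
        assert mean == 7.0 and sd == 0.0

    def test_absent_cell_id(self, small_cell):
        img, mask = small_cell
        with pytest.raises(KeyError):
            cell_intensity_stats(img, mask, 9)

    def test_single_pixel_cell_sample_sd(self):
        img = np.array([[5.0, 0.0]])
        mask = CellMaskSet(np.array([[1, 0]]))
        with pytest.raises(ValueError, match="single-pixel"):
            cell_intensity_stats(img, mask, 1)

    def test_population_sd(self, small_cell):
        img, mask = small_cell
        _, sd, _ = cell_intensity_stats(img, mask, 1, sd_mode="population")
        assert sd == pytest.approx(4.0)  # sqrt(80/5)


class TestSelection:
    def test_hand_fixture_threshold_and_selection(self, hand_cell):
        img, mask = hand_cell
        sel = select_aggregate_pixels(img, mask, 1)
        assert sel.cell_mean == pytest.approx(11.9)
        assert sel.cell_sd == pytest.approx(19.0)  # SSD 35739, var 361
        assert sel.threshold == pytest.approx(68.9)
        assert sel.n_selected == 1
        assert sel.selected[5, 5]

    def test_constant_cell_empty_selection(self):
        img = np.full((3, 3), 5.0)
        mask = CellMaskSet(np.ones((3, 3), dtype=int))
        sel = select_aggregate_pixels(img, mask, 1)
        assert sel.threshold == 5.0
        assert sel.n_selected == 0  # strict '>' leaves a constant cell empty

    def test_small_cell_selection_empty(self, small_cell):
        # threshold 3 + 3*sqrt(20) ~ 16.4 exceeds the max value 11
        img, mask = small_cell
        sel = select_aggregate_pixels(img, mask, 1)
        assert sel.threshold == pytest.approx(3 + 3 * np.sqrt(20))
        assert sel.n_selected == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(4, 33), rng.integers(4, 33))
        img = rng.uniform(0, 100, shape)
        cell = rng.random(shape) < 0.7
        cell.flat[:2] = True  # keep >= 2 pixels
        mask = CellMaskSet(cell.astype(int))
        sel = select_aggregate_pixels(img, mask, 1)
        expected, mean, sd, thr = brute_force_selection(img, cell)
        np.testing.assert_array_equal(sel.selected, expected)
        assert sel.threshold == pytest.approx(thr, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_selection_is_subset_of_cell(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 50, (12, 12))
        cell = np.zeros((12, 12), dtype=int)
        cell[3:9, 3:9] = 1
        sel = select_aggregate_pixels(img, CellMaskSet(cell), 1)
        assert not np.any(sel.selected & (cell == 0))
        vals = img[sel.selected]
        assert np.all(vals > sel.threshold)


class TestPuncta:
    @staticmethod
    def _selection(grid):
        from aggrequant.quant import PixelSelection

        return PixelSelection(1, np.asarray(grid, dtype=bool), 0.0, 1.0, 0.0,
                              int(np.asarray(grid).size))

    def test_two_disjoint_blocks(self):
        grid = np.zeros((10, 10), dtype=bool)
        grid[1:4, 1:4] = True
        grid[6:9, 6:9] = True
        puncta = label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=1))
        assert len(puncta) == 2
        assert sorted(p.area_px for p in puncta) == [9, 9]

    def test_diagonal_touch_connectivity(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[1:3, 1:3] = True
        grid[3:5, 3:5] = True  # touches the first block only diagonally
        p4 = label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=1, connectivity=4))
        p8 = label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=1, connectivity=8))
        assert len(p4) == 2
        assert len(p8) == 1

    def test_min_area_filter(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        assert label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=4)) == []

    def test_centroid_row_col(self):
        grid = np.zeros((7, 7), dtype=bool)
        grid[2:5, 3:6] = True
        (p,) = label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=1))
        assert p.centroid == (3.0, 4.0)

    def test_areas_sum_to_selected_count(self):
        rng = np.random.default_rng(7)
        grid = rng.random((20, 20)) < 0.3
        puncta = label_puncta(self._selection(grid), ThresholdParams(min_punctum_px=1))
        assert sum(p.area_px for p in puncta) == int(grid.sum())


class TestClusteringIndex:
    def test_hand_fixture_value(self, hand_cell):
        img, mask = hand_cell
        sel = select_aggregate_pixels(img, mask, 1)
        assert clustering_index(img, mask, 1, sel) == pytest.approx(200 / 11.9, abs=1e-9)

    def test_empty_selection_is_zero(self):
        img = np.full((4, 4), 3.0)
        mask = CellMaskSet(np.ones((4, 4), dtype=int))
        sel = select_aggregate_pixels(img, mask, 1)
        assert clustering_index(img, mask, 1, sel) == 0.0

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1000.0])
    def test_scale_invariance(self, hand_cell, scale):
        img, mask = hand_cell
        sel1 = select_aggregate_pixels(img, mask, 1)
        sel2 = select_aggregate_pixels(img * scale, mask, 1)
        i1 = clustering_index(img, mask, 1, sel1)
        i2 = clustering_index(img * scale, mask, 1, sel2)
        assert i2 == pytest.approx(i1, rel=1e-9)

    def test_additive_offset_changes_index(self, hand_cell):
        # the index is deliberately NOT offset-invariant
        img, mask = hand_cell
        i1 = clustering_index(img, mask, 1, select_aggregate_pixels(img, mask, 1))
        shifted = img + 50.0
        i2 = clustering_index(shifted, mask, 1, select_aggregate_pixels(shifted, mask, 1))
        assert i1 != pytest.approx(i2)

    def test_zero_mean_nonempty_selection_errors(self):
        from aggrequant.quant import PixelSelection

        img = np.zeros((2, 2))
        mask = CellMaskSet(np.ones((2, 2), dtype=int))
        sel = PixelSelection(1, np.ones((2, 2), dtype=bool), 0.0, 0.0, 0.0, 4)
        with pytest.raises(ZeroDivisionError):
            clustering_index(img, mask, 1, sel)


class TestQuantifyCell:
    def test_hand_fixture_bundle(self, hand_cell):
        img, mask = hand_cell
        res = quantify_cell(img, mask, 1, ThresholdParams(min_punctum_px=1))
        assert res.clustering_index == pytest.approx(200 / 11.9, abs=1e-6)
        assert res.n_puncta == 1
        assert res.total_selected_intensity == 200.0

    def test_constant_cell_zeroes(self):
        img = np.full((5, 5), 9.0)
        mask = CellMaskSet(np.ones((5, 5), dtype=int))
        res = quantify_cell(img, mask, 1)
        assert res.clustering_index == 0.0
        assert res.n_puncta == 0

    def test_batch_two_cells(self):
        img = np.full((4, 8), 10.0)
        img[1, 1] = 100.0
        labels = np.zeros((4, 8), dtype=int)
        labels[:, :4] = 1
        labels[:, 4:] = 2
        results = quantify_all_cells(img, CellMaskSet(labels))
        assert [r.cell_id for r in results] == [1, 2]
        assert results[0].n_selected_px == 1
        assert results[1].n_selected_px == 0

    def test_deterministic(self, hand_cell):
        img, mask = hand_cell
        a = quantify_cell(img, mask, 1)
        b = quantify_cell(img, mask, 1)
        assert a == b
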