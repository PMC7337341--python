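"""Raster stacks, envelope masking, extraction, and geodesic cell areas."""

import numpy as np
import pytest

from hyperniche.occurrences import OccurrenceSet
from hyperniche.rasters import (
    ClimateStack,
    GridSpec,
    apply_envelope_mask,
    cell_area_km2,
    extract_values,
    fit_envelope,
    load_stack,
    read_ascii_grid,
    write_ascii_grid,
)

from conftest import make_occ


class TestAsciiGridIO:
    def test_roundtrip(self, tmp_path):
        grid = GridSpec(3, 4, -10.0, 5.0, 0.25)
        data = np.arange(12, dtype=float).reshape(3, 4)
        data[1, 2] = np.nan
        p = tmp_path / "x.asc"
        write_ascii_grid(p, data, grid)
        back, grid2, nodata = read_ascii_grid(p)
        assert grid2 == grid
        np.testing.assert_array_equal(np.isnan(back), np.isnan(data))
        np.testing.assert_allclose(back[~np.isnan(data)], data[~np.isnan(data)])

    def test_load_stack_alignment_error(self, tmp_path):
        g1 = GridSpec(2, 2, 0, 0, 1.0)
        g2 = GridSpec(3, 2, 0, 0, 1.0)
        write_ascii_grid(tmp_path / "a.asc", np.zeros((2, 2)), g1)
        write_ascii_grid(tmp_path / "b.asc", np.zeros((3, 2)), g2)
        with pytest.raises(ValueError, match="alignment"):
            load_stack([tmp_path / "a.asc", tmp_path / "b.asc"])

    def test_load_stack_names_from_filenames(self, tmp_path):
        g = GridSpec(2, 2, 0, 0, 1.0)
        for n in ("bio01", "bio02"):
            write_ascii_grid(tmp_path / f"{n}.asc", np.ones((2, 2)), g)
        st = load_stack([tmp_path / "bio01.asc", tmp_path / "bio02.asc"])
        assert st.names == ["bio01", "bio02"] and st.k == 2


class TestStack:
    def test_nodata_propagates_across_layers(self, toy_stack):
        # layer a has nodata at (0,0), layer b at (3,3): both cells invalid
        assert not toy_stack.valid_mask[0, 0]
        assert not toy_stack.valid_mask[3, 3]
        assert toy_stack.n_valid == 14

    def test_values_table_excludes_nodata(self, toy_stack):
        values, rows, cols = toy_stack.values_table()
        assert values.shape == (14, 2)
        assert not np.isnan(values).any()


class TestExtract:
    def test_cell_center_lookup(self, toy_stack):
        # grid: xll=0, yll=0, cellsize 1, 4x4; cell (row=2, col=1) center (1.5, 1.5)
        occ = make_occ([(1.5, 1.5, 1950), (0.5, 0.5, 1950), (2.5, 3.5, 1950)])
        values, kept, dropped = extract_values(occ, toy_stack)
        assert values.shape == (3, 2)
        np.testing.assert_allclose(values[0], [9.0, 90.0])  # row 2, col 1
        np.testing.assert_allclose(values[1], [12.0, 120.0])  # row 3, col 0
        np.testing.assert_allclose(values[2], [2.0, 20.0])  # row 0, col 2

    def test_nodata_point_dropped_and_logged(self, toy_stack):
        occ = make_occ([(0.5, 3.5, 1950), (1.5, 1.5, 1950)])  # first on nodata corner
        values, kept, dropped = extract_values(occ, toy_stack)
        assert len(values) == 1
        assert dropped == [(0, "nodata cell")]

    def test_all_points_invalid_is_error(self, toy_stack):
        occ = make_occ([(0.5, 3.5, 1950)])
        with pytest.raises(ValueError):
            extract_values(occ, toy_stack)


class TestEnvelope:
    def test_hand_example(self):
        box = fit_envelope(np.array([[1.0, 5.0], [3.0, 2.0]]))
        np.testing.assert_allclose(box.lo, [1.0, 2.0])
        np.testing.assert_allclose(box.hi, [3.0, 5.0])

    def test_single_point_degenerate(self):
        box = fit_envelope(np.array([[2.0, 7.0]]))
        np.testing.assert_allclose(box.lo, box.hi)
        assert box.contains(np.array([[2.0, 7.0]]))[0]

    def test_envelope_contains_all_training_values(self, stack, occurrences):
        values, _, _ = extract_values(occurrences, stack)
        box = fit_envelope(values)
        assert box.contains(values).all()

    def test_mask_excludes_exactly_out_of_box_cells(self):
        grid = GridSpec(3, 3, 0, 0, 1.0)
        a = np.arange(9, dtype=float).reshape(3, 3)
        b = np.ones((3, 3))
        st = ClimateStack(np.stack([a, b]), ["a", "b"], grid)
        box = fit_envelope(np.array([[0.0, 1.0], [7.0, 1.0]]))  # excludes a=8 corner
        masked = apply_envelope_mask(st, box)
        assert masked.n_valid == 8
        assert not masked.valid_mask[2, 2]

    def test_global_box_changes_nothing(self, toy_stack):
        values, _, _ = toy_stack.values_table(), None, None
        box = fit_envelope(toy_stack.values_table()[0])
        masked = apply_envelope_mask(toy_stack, box)
        assert masked.n_valid == toy_stack.n_valid

    def test_monotone_under_nested_subsets(self, stack, occurrences, scenario):
        from hyperniche.occurrences import cumulative_subsets

        subsets = cumulative_subsets(occurrences, scenario.slicing)
        prev_valid = 0
        for label, sub in subsets:
            values, _, _ = extract_values(sub, stack)
            masked = apply_envelope_mask(stack, fit_envelope(values))
            assert masked.n_valid >= prev_valid
            prev_valid = masked.n_valid


class TestCellArea:
    def test_equatorial_one_degree_cell(self):
        """1°x1° at the equator ≈ 12364 km² (independent spherical formula)."""
        grid = GridSpec(2, 2, 0.0, -1.0, 1.0)  # rows at lat [0,1] and [-1,0]
        area = cell_area_km2(grid, np.array([0]))[0]
        # oracle: R² Δλ (sin 1° − sin 0°), R = 6371.0072
        oracle = 6371.0072**2 * np.radians(1.0) * (np.sin(np.radians(1.0)) - 0.0)
        np.testing.assert_allclose(area, oracle, rtol=1e-12)
        assert abs(area - 12364) / 12364 < 1e-3

    def test_area_decreases_with_latitude(self):
        grid = GridSpec(60, 1, 0.0, 0.0, 1.0)  # rows from 60N down to 0
        areas = cell_area_km2(grid, np.arange(60))
        assert (np.diff(areas) > 0).all()  # towards the equator cells grow
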