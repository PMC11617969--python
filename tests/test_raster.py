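import numpy as np
import pytest

from parkzoning.raster import (CORE, GENERAL, OUTSIDE, LandUseRaster, ZoneMask,
                               read_ascii_grid, read_landuse, read_zone_mask,
                               tessellate, unit_composition, write_raster)

from conftest import make_core_scene


class TestAsciiGridIO:
    def test_integer_round_trip(self, tmp_path, catalog):
        values = np.array([[2, 2, 12], [2, -9999, 11]], dtype=np.int64)
        r = LandUseRaster(values, 100.0, origin=(5000.0, 8000.0))
        path = tmp_path / "r.asc"
        write_raster(r, path)
        back = read_landuse(path, catalog)
        assert np.array_equal(back.values, values)
        assert back.cell_size == 100.0
        assert back.origin == (5000.0, 8000.0)
        assert back.nodata == -9999

    def test_float_round_trip(self, tmp_path):
        vals = np.array([[0.1, np.pi], [1e-9, 42.0]])
        write_raster(LandUseRaster(vals, 400.0), tmp_path / "f.asc")
        back, cell, origin, _ = read_ascii_grid(tmp_path / "f.asc")
        assert np.array_equal(back, vals)  # repr precision -> bit exact
        assert cell == 400.0

    def test_header_written(self, tmp_path):
        write_raster(LandUseRaster(np.ones((2, 3), dtype=np.int64), 50.0),
                     tmp_path / "h.asc")
        text = (tmp_path / "h.asc").read_text().lower()
        for key in ("ncols 3", "nrows 2", "xllcorner", "yllcorner", "cellsize"):
            assert key in text

    def test_unknown_code_listed(self, tmp_path, catalog):
        vals = np.full((4, 4), 99, dtype=np.int64)
        vals[0, 0] = 2
        write_raster(LandUseRaster(vals, 100.0), tmp_path / "u.asc")
        with pytest.raises(ValueError, match=r"\{99: 15\}"):
            read_landuse(tmp_path / "u.asc", catalog)

    def test_mask_alignment_checked(self, tmp_path, catalog):
        write_raster(LandUseRaster(np.full((4, 4), 2, dtype=np.int64), 100.0),
                     tmp_path / "r.asc")
        write_raster(ZoneMask(np.full((3, 4), CORE, dtype=np.int64), 100.0),
                     tmp_path / "m.asc")
        raster = read_landuse(tmp_path / "r.asc", catalog)
        with pytest.raises(ValueError, match="does not match"):
            read_zone_mask(tmp_path / "m.asc", companion=raster)


class TestTessellate:
    def test_full_core_blocks(self):
        raster, mask = make_core_scene(np.full((8, 8), 2))
        grid = tessellate(raster, mask, 400.0)
        assert len(grid) == 4
        assert all(u.area_km2 == pytest.approx(0.16) for u in grid)
        assert all(u.zone == CORE for u in grid)

    def test_boundary_units_keep_partial_area(self):
        values = np.full((8, 8), 2, dtype=np.int64)
        zones = np.full((8, 8), OUTSIDE, dtype=np.int64)
        zones[:, :2] = GENERAL  # park is a 2-column strip
        raster = LandUseRaster(values, 100.0)
        mask = ZoneMask(zones, 100.0)
        grid = tessellate(raster, mask, 400.0)
        assert len(grid) == 2
        assert all(u.area_km2 == pytest.approx(0.08) for u in grid)
        # 0.08 km2 is above the 25% sliver threshold (0.04 km2): not flagged
        assert all(u.flagged is False for u in grid)

    def test_unit_count_near_expected_for_study_scale_footprint(self):
        # a ~586 km2 footprint at 400 m units should give about 3662 units
        zones = np.full((200, 296), OUTSIDE, dtype=np.int64)
        zones[:, :293] = GENERAL  # 58,600 cells x 0.01 km2 = 586 km2
        raster = LandUseRaster(np.full(zones.shape, 2, dtype=np.int64), 100.0)
        grid = tessellate(raster, ZoneMask(zones, 100.0), 400.0)
        assert abs(len(grid) - 3662) / 3662 < 0.02
        assert sum(u.area_km2 for u in grid) == pytest.approx(586.0)

    def test_non_multiple_unit_size_suggests_nearest(self):
        raster, mask = make_core_scene(np.full((8, 8), 2))
        with pytest.raises(ValueError, match="nearest valid value is 400"):
            tessellate(raster, mask, 350.0)

    def test_deterministic_ids(self):
        raster, mask = make_core_scene(np.full((8, 8), 2))
        g1 = tessellate(raster, mask, 400.0)
        g2 = tessellate(raster, mask, 400.0)
        assert [u.unit_id for u in g1] == [u.unit_id for u in g2]
        assert [u.row_slice for u in g1] == [u.row_slice for u in g2]


class TestComposition:
    def test_single_class_unit(self):
        raster, mask = make_core_scene(np.full((4, 4), 2))
        grid = unit_composition(tessellate(raster, mask, 400.0), raster, mask)
        assert grid.units[0].class_areas == {2: pytest.approx(0.16)}

    def test_mixed_unit(self):
        values = np.full((4, 4), 2, dtype=np.int64)
        values[0, :] = 9  # 4 cells irrigated field
        raster, mask = make_core_scene(values)
        grid = unit_composition(tessellate(raster, mask, 400.0), raster, mask)
        areas = grid.units[0].class_areas
        assert areas[2] == pytest.approx(0.12)
        assert areas[9] == pytest.approx(0.04)

    def test_area_conservation_exact(self):
        rng = np.random.default_rng(5)
        values = rng.integers(1, 13, size=(37, 53))
        zones = (rng.random((37, 53)) < 0.8).astype(np.int64) * GENERAL
        raster = LandUseRaster(values, 100.0)
        mask = ZoneMask(zones, 100.0)
        grid = unit_composition(tessellate(raster, mask, 400.0), raster, mask)
        total = sum(a for u in grid for a in u.class_areas.values())
        n_park = int(np.count_nonzero(zones != OUTSIDE))
        assert total == pytest.approx(n_park * 0.01, abs=1e-12)
        # nodata-free raster: per-unit class areas exhaust A_k
        for u in grid:
            assert sum(u.class_areas.values()) == pytest.approx(u.area_km2)

    def test_nodata_reduces_class_areas_not_unit_area(self):
        values = np.full((4, 4), 2, dtype=np.int64)
        values[1, 1] = -9999
        raster, mask = make_core_scene(values)
        grid = unit_composition(tessellate(raster, mask, 400.0), raster, mask)
        u = grid.units[0]
        assert u.area_km2 == pytest.approx(0.16)
        assert sum(u.class_areas.values()) == pytest.approx(0.15)
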