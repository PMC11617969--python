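import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from parkzoning.classify import (CHR, CLR, GHE, GLE, NONE, BreakSet,
                                 apply_grades, four_zone_map, jenks_breaks,
                                 zone_area_from_grades, zone_report)
from parkzoning.raster import CORE, GENERAL, tessellate, unit_composition
from parkzoning.kriging import krige, VariogramModel

from conftest import make_core_scene


def within_class_ss(sorted_vals, starts):
    """Total within-class sum of squares for classes starting at `starts`."""
    bounds = list(starts) + [len(sorted_vals)]
    total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        chunk = np.asarray(sorted_vals[a:b])
        total += float(((chunk - chunk.mean()) ** 2).sum())
    return total


def exhaustive_best_ss(values, k):
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        best = min(best, within_class_ss(x, (0,) + cuts))
    return best


def dp_ss(values, k):
    x = np.sort(np.asarray(values, dtype=float))
    brk = jenks_breaks(x, k)
    starts = [0] + [int(np.searchsorted(x, b, side="left")) for b in brk.breaks]
    return within_class_ss(x, starts)


class TestJenksBreaks:
    def test_two_obvious_clusters(self):
        brk = jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert brk.breaks == (10.0,)
        assert list(brk.grade([1, 2, 3, 10, 11, 12])) == [1, 1, 1, 2, 2, 2]

    def test_four_values_minimum_ss(self):
        brk = jenks_breaks([4, 5, 9, 10], k=2)
        assert brk.breaks == (9.0,)
        assert dp_ss([4, 5, 9, 10], 2) == pytest.approx(1.0)

    def test_k1_has_no_breaks(self):
        assert jenks_breaks([3, 1, 2], k=1).breaks == ()

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            jenks_breaks([1.0, 1.0, 2.0], k=3)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        k = int(rng.integers(2, 5))
        values = rng.normal(0, 10, n).round(2)
        if len(np.unique(values)) < k:
            return
        assert dp_ss(values, k) == pytest.approx(
            exhaustive_best_ss(values, k), abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=6, max_size=12),
           st.integers(2, 4))
    def test_oracle_property(self, values, k):
        if len(set(values)) < k:
            return
        assert dp_ss(values, k) == pytest.approx(
            exhaustive_best_ss(values, k), abs=1e-9)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 5, 40)
        b1 = jenks_breaks(values, 4)
        b2 = jenks_breaks(3.0 * values + 7.0, 4)
        assert np.allclose(np.array(b2.breaks), 3.0 * np.array(b1.breaks) + 7.0)
        assert np.array_equal(b1.grade(values), b2.grade(3.0 * values + 7.0))


class TestApplyGrades:
    eri_breaks = BreakSet(5, (0.016, 0.063, 0.180, 0.431), 0.001, 0.6)

    def test_boundary_value_goes_to_upper_grade(self):
        # a value exactly on the first break belongs to grade II
        assert self.eri_breaks.grade([0.016])[0] == 2

    def test_below_first_break_is_grade_one(self):
        assert self.eri_breaks.grade([0.0159])[0] == 1

    def test_maximum_lands_in_top_grade(self):
        assert self.eri_breaks.grade([0.6])[0] == 5

    def test_nan_maps_to_zero(self):
        gm = apply_grades(np.array([np.nan, 0.1]), self.eri_breaks)
        assert list(gm.grades) == [0, 3]


def _fitted_scene(catalog):
    """Small two-zone scene kriged onto the unit grid."""
    rng = np.random.default_rng(20)
    values = rng.integers(1, 13, size=(32, 32))
    raster, mask = make_core_scene(values)
    mask.values[:, 16:] = GENERAL
    grid = unit_composition(tessellate(raster, mask, 400.0), raster, mask)
    from parkzoning.eri import eri_field
    from parkzoning.esv import esv_field
    ef, _ = eri_field(grid, raster, mask, catalog)
    vf = esv_field(grid, raster, mask, catalog)
    model = VariogramModel("spherical", 0.0, 1.0, 800.0)
    es = krige(ef.samples(), model, grid, CORE, kind="ERI")
    vs = krige(vf.samples(), model, grid, GENERAL, kind="ESV")
    return grid, es, vs


class TestFourZoneMap:
    def test_threshold_semantics(self, catalog):
        grid, es, vs = _fitted_scene(catalog)
        eb = jenks_breaks(es.values[~np.isnan(es.values)], 5)
        vb = jenks_breaks(vs.values[~np.isnan(vs.values)], 5)
        zoning = four_zone_map(es, vs, grid, eri_breaks=eb, esv_breaks=vb)
        assert zoning.eri_cut == eb.breaks[0]
        assert zoning.esv_cut == vb.breaks[1]
        for u in grid.units:
            code = zoning.values[u.unit_id]
            if u.zone == CORE:
                assert code == (CHR if es.values[u.unit_id] >= zoning.eri_cut else CLR)
            else:
                assert code == (GHE if vs.values[u.unit_id] >= zoning.esv_cut else GLE)

    def test_explicit_cuts_override_breaks(self, catalog):
        grid, es, vs = _fitted_scene(catalog)
        zoning = four_zone_map(es, vs, grid, eri_cut=0.02, esv_cut=71.10)
        assert (zoning.eri_cut, zoning.esv_cut) == (0.02, 71.10)
        # a general unit exactly at the cut is GHE (boundary to upper class)
        vs.values[grid.in_zone(GENERAL)[0].unit_id] = 71.10
        zoning = four_zone_map(es, vs, grid, eri_cut=0.02, esv_cut=71.10)
        assert zoning.values[grid.in_zone(GENERAL)[0].unit_id] == GHE

    def test_cells_without_units_are_none(self, catalog):
        grid, es, vs = _fitted_scene(catalog)
        zoning = four_zone_map(es, vs, grid, eri_cut=0.0, esv_cut=0.0)
        unit_cells = {u.unit_id for u in grid.units}
        for rid in np.ndindex(zoning.values.shape):
            if rid not in unit_cells:
                assert zoning.values[rid] == NONE


class TestZoneReport:
    def test_partition_and_percent_sum(self, catalog):
        grid, es, vs = _fitted_scene(catalog)
        eb = jenks_breaks(es.values[~np.isnan(es.values)], 5)
        vb = jenks_breaks(vs.values[~np.isnan(vs.values)], 5)
        zoning = four_zone_map(es, vs, grid, eri_breaks=eb, esv_breaks=vb)
        rep = zone_report(zoning, grid, apply_grades(es, eb), apply_grades(vs, vb))
        park = sum(u.area_km2 for u in grid.units)
        assert rep.zones["area_km2"].sum() == pytest.approx(park, abs=1e-9)
        assert rep.zones["percent"].sum() == pytest.approx(100.0, abs=0.02)

    def test_ghe_equals_upper_grade_areas(self, catalog):
        # esv cut = second break -> GHE area = areas of ESV grades III + IV + V
        grid, es, vs = _fitted_scene(catalog)
        eb = jenks_breaks(es.values[~np.isnan(es.values)], 5)
        vb = jenks_breaks(vs.values[~np.isnan(vs.values)], 5)
        zoning = four_zone_map(es, vs, grid, eri_breaks=eb, esv_breaks=vb)
        rep = zone_report(zoning, grid, apply_grades(es, eb), apply_grades(vs, vb))
        esv_grades = rep.grades[rep.grades["field"] == "ESV"]
        grade_areas = dict(zip(esv_grades["grade"], esv_grades["area_km2"]))
        assert rep.zone_area("GHE") == pytest.approx(
            zone_area_from_grades(grade_areas, 3), abs=1e-9)

    def test_constant_fields_split_by_mask_proportion(self, catalog):
        grid, es, vs = _fitted_scene(catalog)
        es.values[~np.isnan(es.values)] = 1.0
        vs.values[~np.isnan(vs.values)] = 1.0
        zoning = four_zone_map(es, vs, grid, eri_cut=2.0, esv_cut=0.5)
        rep = zone_report(zoning, grid)
        core_area = sum(u.area_km2 for u in grid.in_zone(CORE))
        assert rep.zone_area("CLR") == pytest.approx(core_area)
        assert rep.zone_area("CHR") == 0.0
        assert rep.zone_area("GHE") == pytest.approx(
            rep.park_area_km2 - core_area)
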