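import numpy as np
import pytest

from parkzoning.metrics import class_metrics, label_patches
from parkzoning.raster import CORE
from parkzoning.synthetic import fixture_raster

from conftest import make_core_scene


def flood_fill_count(binary: np.ndarray, connectivity: int) -> int:
    """Independent stack-based flood-fill patch counter (test oracle)."""
    offsets4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    offsets = offsets4 + ([(-1, -1), (-1, 1), (1, -1), (1, 1)]
                          if connectivity == 8 else [])
    seen = np.zeros_like(binary, dtype=bool)
    n = 0
    rows, cols = binary.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if binary[r0, c0] and not seen[r0, c0]:
                n += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < rows and 0 <= cc < cols
                                and binary[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return n


class TestLabelPatches:
    def test_diagonal_pair_connectivity(self):
        raster, mask, expected = fixture_raster("diag-pair")
        region = mask.values == CORE
        assert label_patches(raster, region, 12, 8).n_patches == expected["n_patches_conn8"]
        assert label_patches(raster, region, 12, 4).n_patches == expected["n_patches_conn4"]

    def test_absent_class_zero_patches(self):
        raster, mask = make_core_scene(np.full((3, 3), 2))
        assert label_patches(raster, mask.values == CORE, 11).n_patches == 0

    def test_patch_cells_sum_to_class_cells(self):
        rng = np.random.default_rng(0)
        raster, mask = make_core_scene(rng.integers(1, 4, size=(20, 20)))
        lab = label_patches(raster, mask.values == CORE, 2)
        assert lab.total_cells == int(np.count_nonzero(raster.values == 2))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(60):
            shape = rng.integers(2, 31, size=2)
            raster, mask = make_core_scene(rng.integers(1, 3, size=tuple(shape)))
            lab = label_patches(raster, mask.values == CORE, 2, connectivity)
            assert lab.n_patches == flood_fill_count(raster.values == 2, connectivity)


class TestClassMetrics:
    def test_single_class_closed_form(self, catalog):
        raster, mask, expected = fixture_raster("single-class-4km2")
        t = class_metrics(raster, mask.values == CORE, catalog).table.loc[2]
        assert t["C_i"] == pytest.approx(expected["C_i"])
        assert t["N_i"] == pytest.approx(expected["N_i"])
        assert t["D_i"] == pytest.approx(expected["D_i"])
        assert t["S_i"] == pytest.approx(expected["S_i"])

    def test_patch_split_raises_fragmentation_and_disturbance(self, catalog):
        # same A and A_i (4 km2), but the single patch split in two by a
        # nodata gap: C_i doubles from 0.25 to 0.5 and S_i strictly increases
        one = np.full((1, 4), 2, dtype=np.int64)
        r1, m1 = make_core_scene(one, cell_size=1000.0)
        two = np.array([[2, 2, -9999, 2, 2]], dtype=np.int64)
        r2, m2 = make_core_scene(two, cell_size=1000.0)
        t1 = class_metrics(r1, m1.values == CORE, catalog, connectivity=4).table.loc[2]
        t2 = class_metrics(r2, m2.values == CORE, catalog, connectivity=4).table.loc[2]
        assert (t1["n_i"], t2["n_i"]) == (1, 2)
        assert t1["C_i"] == pytest.approx(0.25)
        assert t2["C_i"] == pytest.approx(0.5)
        # hand-derived: S1 = 0.325, S2 = 0.6*0.5 + 0.3*(0.5*sqrt(0.5)) + 0.1
        assert t1["S_i"] == pytest.approx(0.325)
        assert t2["S_i"] == pytest.approx(0.6 * 0.5 + 0.3 * 0.5 * np.sqrt(0.5) + 0.1)
        assert t2["S_i"] > t1["S_i"]

    def test_two_equal_classes_symmetric_dominance(self, catalog):
        values = np.full((4, 4), 2, dtype=np.int64)
        values[:, 2:] = 11
        raster, mask = make_core_scene(values)
        t = class_metrics(raster, mask.values == CORE, catalog).table
        for code in (2, 11):
            assert t.loc[code, "M_i"] == pytest.approx(0.5)
            assert t.loc[code, "L_i"] == pytest.approx(0.5)
            assert t.loc[code, "D_i"] == pytest.approx(0.5)

    def test_shares_sum_to_one(self, catalog):
        rng = np.random.default_rng(3)
        raster, mask = make_core_scene(rng.integers(1, 13, size=(30, 30)))
        t = class_metrics(raster, mask.values == CORE, catalog).table
        assert t["M_i"].sum() == pytest.approx(1.0, abs=1e-9)
        assert t["L_i"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (t["D_i"] <= 1.0).all()
        assert (t >= 0).all().all()

    def test_cell_size_rescaling(self, catalog):
        rng = np.random.default_rng(4)
        values = rng.integers(1, 5, size=(16, 16))
        r100, m100 = make_core_scene(values, cell_size=100.0)
        r200, m200 = make_core_scene(values, cell_size=200.0)
        t100 = class_metrics(r100, m100.values == CORE, catalog)
        t200 = class_metrics(r200, m200.values == CORE, catalog)
        assert t200.landscape_area_km2 == pytest.approx(4 * t100.landscape_area_km2)
        for code in t100.table.index:
            assert t200.table.loc[code, "A_i_km2"] == pytest.approx(
                4 * t100.table.loc[code, "A_i_km2"])
            assert t200.table.loc[code, "C_i"] == pytest.approx(
                t100.table.loc[code, "C_i"] / 4)
            assert t200.table.loc[code, "D_i"] == pytest.approx(
                t100.table.loc[code, "D_i"])

    def test_empty_region_rejected(self, catalog):
        raster, mask = make_core_scene(np.full((3, 3), 2))
        with pytest.raises(ValueError, match="empty"):
            class_metrics(raster, np.zeros((3, 3), bool), catalog)

    def test_stray_class_rejected(self, catalog):
        raster, mask = make_core_scene(np.full((3, 3), 99))
        with pytest.raises(ValueError, match="99"):
            class_metrics(raster, mask.values == CORE, catalog)
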