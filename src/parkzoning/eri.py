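"""Per-class loss index and per-unit Ecological Risk Index (ERI).

The loss index of class *i* couples its vulnerability rank with its landscape
disturbance: ``R_i = F̂_i * S_i``, where ``F̂_i`` is the vulnerability rank
normalized by the catalog rank sum (78 for the 12-rank legend) — raw ranks can
be used instead; the choice rescales every ``R_i`` by the same constant and is
therefore immaterial to natural-breaks grading downstream.

The per-unit index is the composition-weighted average
``ERI_k = sum_i (A_ki / A_k) R_i``: a convex combination of the ``R_i`` of the
classes present in the unit, so risk is high where vulnerable, fragmented
classes dominate the unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import DEFAULT_WEIGHTS, class_metrics
from .raster import CORE, AssessmentGrid, AssessmentUnit, unit_composition

__all__ = ["LossIndexTable", "ScalarField", "loss_index", "unit_eri", "eri_field"]


@dataclass
class LossIndexTable:
    """Per-class F_i, normalized F̂_i, disturbance S_i and loss R_i."""

    table: pd.DataFrame  # index: class code; columns F_i, F_hat, S_i, R_i
    normalized: bool

    def r_index(self) -> dict[int, float]:
        return self.table["R_i"].to_dict()


@dataclass
class ScalarField:
    """Per-assessment-unit values of one quantity (ERI or ESV) in one zone."""

    kind: str                       # "ERI" or "ESV"
    zone: int
    units: list[AssessmentUnit]
    values: np.ndarray              # one value per unit, aligned with `units`
    breakdown: pd.DataFrame | None = None  # optional per-unit extras

    def __len__(self) -> int:
        return len(self.units)

    def samples(self, include_flagged: bool = False) -> np.ndarray:
        """(x, y, value) rows for interpolation; sliver units excluded by default."""
        rows = [
            (u.centroid[0], u.centroid[1], v)
            for u, v in zip(self.units, self.values)
            if include_flagged or not u.flagged
        ]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "row_block": [u.unit_id[0] for u in self.units],
            "col_block": [u.unit_id[1] for u in self.units],
            "x": [u.centroid[0] for u in self.units],
            "y": [u.centroid[1] for u in self.units],
            "A_k_km2": [u.area_km2 for u in self.units],
            self.kind: self.values,
        })
        if self.breakdown is not None:
            df = pd.concat([df, self.breakdown.reset_index(drop=True)], axis=1)
        return df


def loss_index(metrics, catalog, normalize_F: bool = True) -> LossIndexTable:
    """R_i = F̂_i * S_i per class of the metrics table.

    ``normalize_F`` divides each rank by the catalog rank sum so that loss
    indices (and hence ERI) land on a 0–1-ish scale; switching it off scales
    all values by the same constant.
    """
    rank_sum = catalog.rank_sum()
    rows = []
    for code, row in metrics.table.iterrows():
        cls = catalog.by_code(int(code))  # raises KeyError for stray classes
        F = cls.vulnerability_rank
        F_hat = F / rank_sum if normalize_F else float(F)
        rows.append({
            "code": int(code), "F_i": F, "F_hat": F_hat,
            "S_i": row["S_i"], "R_i": F_hat * row["S_i"],
        })
    return LossIndexTable(pd.DataFrame(rows).set_index("code"), normalize_F)


def unit_eri(unit: AssessmentUnit, loss: LossIndexTable) -> float:
    """ERI_k = sum_i (A_ki / A_k) R_i over the classes present in the unit."""
    if not unit.area_km2 > 0:
        raise ValueError(f"unit {unit.unit_id} has zero in-park area")
    r = loss.r_index()
    total = 0.0
    for code, a_ki in sorted(unit.class_areas.items()):
        if code not in r:
            raise KeyError(
                f"unit {unit.unit_id}: class {code} has no loss index "
                "(was it absent from the metrics region?)"
            )
        total += (a_ki / unit.area_km2) * r[code]
    return total


def eri_field(
    grid: AssessmentGrid,
    raster,
    mask,
    catalog,
    connectivity: int = 8,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    normalize_F: bool = True,
    scope: str = "landscape-global",
    zone: int = CORE,
) -> tuple[ScalarField, LossIndexTable]:
    """ERI_k for every unit of ``zone`` (the core protected area by default).

    Under the default landscape-global scope one loss table is computed over
    the whole zone and shared by all units; under ``scope="per-unit"`` metrics
    and loss are recomputed inside each unit's window.
    """
    if scope not in ("landscape-global", "per-unit"):
        raise ValueError("scope must be 'landscape-global' or 'per-unit'")
    units = grid.in_zone(zone)
    if not units:
        raise ValueError("no assessment units in the requested zone")
    if not all(u.class_areas or u.area_km2 == 0 for u in units):
        unit_composition(grid, raster, mask)

    region = mask.values == zone
    metrics = class_metrics(raster, region, catalog, connectivity, weights)
    loss = loss_index(metrics, catalog, normalize_F)

    values = np.empty(len(units))
    if scope == "landscape-global":
        for j, u in enumerate(units):
            values[j] = unit_eri(u, loss)
    else:
        for j, u in enumerate(units):
            r0, r1 = u.row_slice
            c0, c1 = u.col_slice
            window = np.zeros_like(region)
            window[r0:r1, c0:c1] = region[r0:r1, c0:c1]
            local = class_metrics(raster, window, catalog, connectivity, weights)
            values[j] = unit_eri(u, loss_index(local, catalog, normalize_F))
    return ScalarField("ERI", zone, units, values), loss
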