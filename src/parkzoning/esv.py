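"""Per-unit Ecosystem Service Value (ESV) and the four-category service report.

The equivalent-factor method prices each land-use class per km² via the
catalog's coefficient table ``VC_i``, so a unit's value is simply
``ESV_k = sum_i A_ki * VC_i`` (in 万元, RMB 10⁴). Category breakdowns
(provisioning / regulating / supporting / cultural) use the category-restricted
columns of ``VC_i`` and therefore partition ``ESV_k`` exactly.

Totals use compensated summation (``math.fsum``) so reported values are
independent of unit ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import SERVICE_CATEGORIES, coefficient_table
from .eri import ScalarField
from .raster import GENERAL, AssessmentGrid, AssessmentUnit, unit_composition

__all__ = ["ServiceValueReport", "unit_esv", "esv_field", "service_report"]


@dataclass
class ServiceValueReport:
    """Category totals (万元), shares (%), and the grand total (万元 and RMB million)."""

    values: dict[str, float]        # category -> 万元, unrounded
    percentages: dict[str, float]   # category -> %, rounded to 2 dp
    total: float                    # 万元, unrounded
    total_million_rmb: float        # RMB million, rounded to 2 dp
    degenerate: bool = False        # True when the total is zero (percentages undefined)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"service_type": f"{cat.capitalize()} services",
             "value_wanyuan": _round2(self.values[cat]),
             "percent": self.percentages[cat]}
            for cat in SERVICE_CATEGORIES
        ]
        return pd.DataFrame(rows)


def _round2(x: float) -> float:
    """Half-even rounding to 2 decimals, applied at the report layer only."""
    return float(np.round(x, 2))


def unit_esv(unit: AssessmentUnit, vc_table: dict[int, dict[str, float]]):
    """ESV_k (万元) plus its per-category breakdown for one unit.

    Returns ``(esv_k, {category: value})``; the category values sum to
    ``esv_k`` up to float associativity because the VC columns partition the
    total coefficient.
    """
    cat_vals = {cat: [] for cat in SERVICE_CATEGORIES}
    for code, a_ki in sorted(unit.class_areas.items()):
        if code not in vc_table:
            raise KeyError(f"unit {unit.unit_id}: class {code} has no VC row")
        vc = vc_table[code]
        for cat, subs in SERVICE_CATEGORIES.items():
            cat_vals[cat].append(a_ki * math.fsum(vc[s] for s in subs))
    breakdown = {cat: math.fsum(vals) for cat, vals in cat_vals.items()}
    return math.fsum(breakdown.values()), breakdown


def esv_field(
    grid: AssessmentGrid,
    raster,
    mask,
    catalog,
    zone: int = GENERAL,
) -> ScalarField:
    """ESV_k for every unit of ``zone`` (the general control area by default)."""
    units = grid.in_zone(zone)
    if not units:
        raise ValueError("no assessment units in the requested zone")
    if not all(u.class_areas or u.area_km2 == 0 for u in units):
        unit_composition(grid, raster, mask)
    vc = coefficient_table(catalog)
    values = np.empty(len(units))
    rows = []
    for j, u in enumerate(units):
        values[j], breakdown = unit_esv(u, vc)
        rows.append({f"esv_{cat}": v for cat, v in breakdown.items()})
    return ScalarField("ESV", zone, units, values, breakdown=pd.DataFrame(rows))


def service_report(field_or_values) -> ServiceValueReport:
    """Aggregate a field's per-unit category breakdowns into the category report.

    Accepts either a :class:`~parkzoning.eri.ScalarField` produced by
    :func:`esv_field` (its breakdown columns are summed with compensated
    summation) or a ready ``{category: total 万元}`` mapping. Percentages are
    ``value / total x 100`` rounded to 2 dp; the grand total is also expressed
    in RMB million (万元 / 100, 2 dp).
    """
    if isinstance(field_or_values, dict):
        values = {cat: float(field_or_values[cat]) for cat in SERVICE_CATEGORIES}
    else:
        field = field_or_values
        if field.breakdown is None or len(field) == 0:
            raise ValueError("field carries no per-category breakdown")
        values = {
            cat: math.fsum(field.breakdown[f"esv_{cat}"].tolist())
            for cat in SERVICE_CATEGORIES
        }
    total = math.fsum(values.values())
    if total == 0:
        return ServiceValueReport(
            values, {cat: float("nan") for cat in values}, 0.0, 0.0, degenerate=True
        )
    percentages = {cat: _round2(100.0 * v / total) for cat, v in values.items()}
    return ServiceValueReport(values, percentages, total, _round2(total / 100.0))
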