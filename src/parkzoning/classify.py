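"""Natural-breaks grading and the four-zone (CHR/CLR/GHE/GLE) synthesis.

Grading uses exact Fisher–Jenks dynamic programming (minimum within-class sum
of squared deviations). Grade intervals are half-open with boundary values in
the *upper* class: grade 1 is ``value < b_1``, grade j is ``b_{j-1} <= value <
b_j``, grade k is ``value >= b_{k-1}``; a reported break equals the smallest
value of its upper class.

The four-zone map splits the core protected area at an ERI cut (by default the
first ERI break, so CHR = ERI grades II–V) and the general control area at an
ESV cut (by default the second ESV break, so GHE = ESV grades III–V). The cuts
are data-driven because the method, not the source study's numbers, transfers
to new rasters; fixed numeric cuts can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import CORE, GENERAL, AssessmentGrid

__all__ = [
    "CHR", "CLR", "GHE", "GLE", "NONE", "ZONE_LABELS",
    "BreakSet", "GradeMap", "ZoningMap", "ZoneReport",
    "jenks_breaks", "apply_grades", "four_zone_map", "zone_report",
    "zone_area_from_grades",
]

# Zoning codes (raster values of the four-zone map).
CHR, CLR, GHE, GLE, NONE = 1, 2, 3, 4, 5
ZONE_LABELS = {CHR: "CHR", CLR: "CLR", GHE: "GHE", GLE: "GLE", NONE: "NONE"}

_MAX_JENKS_N = 4000  # above this, breaks are computed on an even-stride subsample


@dataclass(frozen=True)
class BreakSet:
    k: int
    breaks: tuple[float, ...]  # ascending, length k-1
    vmin: float
    vmax: float

    def grade(self, values) -> np.ndarray:
        """Half-open grade assignment; boundary-equal values go to the upper class."""
        v = np.asarray(values, dtype=float)
        g = np.searchsorted(np.asarray(self.breaks), v, side="right") + 1
        return np.where(np.isnan(v), 0, g).astype(int)


@dataclass
class GradeMap:
    grades: np.ndarray  # int array on the surface grid; 0 = outside
    breakset: BreakSet
    kind: str = ""


@dataclass
class ZoningMap:
    values: np.ndarray  # int array on the surface (assessment-unit) grid
    eri_cut: float
    esv_cut: float


@dataclass
class ZoneReport:
    zones: pd.DataFrame       # zone, area_km2, percent
    grades: pd.DataFrame      # field kind, grade, area_km2, percent (within its zone family)
    park_area_km2: float

    def zone_area(self, label: str) -> float:
        row = self.zones[self.zones["zone"] == label]
        return float(row["area_km2"].iloc[0]) if len(row) else 0.0


def _ssq_prefix(x: np.ndarray):
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def jenks_breaks(values, k: int = 5) -> BreakSet:
    """Exact Fisher–Jenks natural breaks of ``values`` into ``k`` classes.

    Dynamic programming over the sorted values minimizes the total
    within-class sum of squared deviations; the result is deterministic. Each
    reported break is the smallest value of its upper class. For very large
    inputs (> 4000 values) the optimization runs on an even-stride subsample
    of the sorted values; grading of the full data is unaffected by this.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no values to classify")
    vmin, vmax = float(x.min()), float(x.max())
    distinct = np.unique(x)
    if distinct.size < k:
        raise ValueError(
            f"only {distinct.size} distinct values; choose k <= {distinct.size}"
        )
    if k == 1:
        return BreakSet(1, (), vmin, vmax)
    x = np.sort(x)
    if x.size > _MAX_JENKS_N:
        idx = np.unique(np.linspace(0, x.size - 1, _MAX_JENKS_N).round().astype(int))
        x = x[idx]
    n = x.size
    s1, s2 = _ssq_prefix(x)

    def ssq(j, i):
        # within-class SS of x[j..i] inclusive, 0-based
        m = i - j + 1
        s = s1[i + 1] - s1[j]
        return s2[i + 1] - s2[j] - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n), INF)
    cut = np.zeros((k + 1, n), dtype=int)
    for i in range(n):
        cost[1, i] = ssq(0, i)
    for m in range(2, k + 1):
        for i in range(m - 1, n):
            j = np.arange(m - 1, i + 1)           # last class = x[j..i]
            cnt = i - j + 1
            s = s1[i + 1] - s1[j]
            last = s2[i + 1] - s2[j] - s * s / cnt
            tot = cost[m - 1, j - 1] + last
            b = int(np.argmin(tot))
            cost[m, i] = tot[b]
            cut[m, i] = j[b]
    # recover class start indices
    breaks = []
    i = n - 1
    for m in range(k, 1, -1):
        j = cut[m, i]
        breaks.append(float(x[j]))  # smallest value of the upper class
        i = j - 1
    breaks.reverse()
    return BreakSet(k, tuple(breaks), vmin, vmax)


def apply_grades(surface_or_values, breakset: BreakSet, kind: str = "") -> GradeMap:
    """Grade a kriged surface (or any value array/field) with a break set.

    NaN cells (outside the zone) get grade 0.
    """
    vals = getattr(surface_or_values, "values", surface_or_values)
    kind = kind or getattr(surface_or_values, "kind", "")
    return GradeMap(breakset.grade(vals), breakset, kind)


def four_zone_map(
    eri_surface,
    esv_surface,
    grid: AssessmentGrid,
    eri_breaks: BreakSet | None = None,
    esv_breaks: BreakSet | None = None,
    eri_cut: float | None = None,
    esv_cut: float | None = None,
) -> ZoningMap:
    """Synthesize the CHR/CLR/GHE/GLE map on the assessment-unit grid.

    Core units with ``ERI >= eri_cut`` become CHR, the rest CLR; general units
    with ``ESV >= esv_cut`` become GHE, the rest GLE. Cuts default to the
    first ERI break and the second ESV break. Cells with no assessment unit
    are NONE.
    """
    ev, sv = eri_surface.values, esv_surface.values
    if ev.shape != sv.shape:
        raise ValueError("ERI and ESV surfaces are not aligned")
    if eri_cut is None:
        if eri_breaks is None or not eri_breaks.breaks:
            raise ValueError("need eri_breaks or an explicit eri_cut")
        eri_cut = eri_breaks.breaks[0]
    if esv_cut is None:
        if esv_breaks is None or len(esv_breaks.breaks) < 2:
            raise ValueError("need esv_breaks (k >= 3) or an explicit esv_cut")
        esv_cut = esv_breaks.breaks[1]
    zoning = np.full(ev.shape, NONE, dtype=int)
    for u in grid.units:
        rid = u.unit_id
        if u.zone == CORE:
            if np.isnan(ev[rid]):
                raise ValueError(f"core unit {rid} has no ERI surface value")
            zoning[rid] = CHR if ev[rid] >= eri_cut else CLR
        else:
            if np.isnan(sv[rid]):
                raise ValueError(f"general unit {rid} has no ESV surface value")
            zoning[rid] = GHE if sv[rid] >= esv_cut else GLE
    return ZoningMap(zoning, float(eri_cut), float(esv_cut))


def zone_area_from_grades(grade_areas: dict[int, float], first_grade: int) -> float:
    """Area of the upper zone implied by a cut at the lower bound of ``first_grade``.

    Under the half-open convention a cut equal to a break makes the high zone
    exactly the union of the grades at and above the break, so its area is the
    sum of those grade areas.
    """
    return sum(a for g, a in grade_areas.items() if g >= first_grade)


def zone_report(
    zoning: ZoningMap,
    grid: AssessmentGrid,
    eri_grades: GradeMap | None = None,
    esv_grades: GradeMap | None = None,
) -> ZoneReport:
    """Area and percentage accounting of zones (and, optionally, grades).

    Areas use each unit's true in-park area ``A_k`` (boundary units count
    fractionally), so the four zones partition the park area exactly.
    """
    zone_area = {code: 0.0 for code in (CHR, CLR, GHE, GLE)}
    park_area = 0.0
    grade_rows: dict[tuple[str, int], float] = {}
    for u in grid.units:
        code = int(zoning.values[u.unit_id])
        if code == NONE:
            continue
        zone_area[code] += u.area_km2
        park_area += u.area_km2
        for gm, kind_zone in ((eri_grades, CORE), (esv_grades, GENERAL)):
            if gm is not None and u.zone == kind_zone:
                g = int(gm.grades[u.unit_id])
                key = (gm.kind, g)
                grade_rows[key] = grade_rows.get(key, 0.0) + u.area_km2
    zones = pd.DataFrame([
        {"zone": ZONE_LABELS[code], "area_km2": area,
         "percent": 100.0 * area / park_area if park_area else float("nan")}
        for code, area in zone_area.items()
    ])
    family_tot = {}
    for (kind, _), a in grade_rows.items():
        family_tot[kind] = family_tot.get(kind, 0.0) + a
    grades = pd.DataFrame([
        {"field": kind, "grade": g, "area_km2": a,
         "percent": 100.0 * a / family_tot[kind]}
        for (kind, g), a in sorted(grade_rows.items())
    ])
    return ZoneReport(zones, grades, park_area)
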