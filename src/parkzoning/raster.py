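"""Raster containers, ESRI ASCII grid I/O, tessellation and unit composition.

Conventions, fixed for reproducibility:

* arrays are north-up: row 0 is the northernmost row;
* rows/cols are 0-based, cells are half-open intervals of the grid;
* assessment units are square blocks of raster cells anchored at the raster
  origin (upper-left corner), identified by ``(row_block, col_block)``;
* areas are km² throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CORE",
    "GENERAL",
    "OUTSIDE",
    "LandUseRaster",
    "ZoneMask",
    "AssessmentUnit",
    "AssessmentGrid",
    "read_landuse",
    "read_zone_mask",
    "read_ascii_grid",
    "write_raster",
    "tessellate",
    "unit_composition",
]

# Zone codes of the park mask raster.
OUTSIDE, CORE, GENERAL = 0, 1, 2
_ZONE_NAMES = {OUTSIDE: "OUTSIDE", CORE: "CORE", GENERAL: "GENERAL"}


@dataclass
class LandUseRaster:
    """A categorical land-use grid.

    ``values`` holds integer class codes (or ``nodata``); ``cell_size`` is the
    side of one cell in meters; ``origin`` is the (x, y) map coordinate of the
    upper-left corner of the upper-left cell.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)


@dataclass
class ZoneMask(LandUseRaster):
    """Core / general / outside partition on the same grid as the land-use raster."""

    def zone_name(self, code: int) -> str:
        return _ZONE_NAMES.get(code, f"?{code}")


@dataclass
class AssessmentUnit:
    """One square assessment unit (grid cell of the coarse evaluation grid)."""

    unit_id: tuple[int, int]           # (row_block, col_block)
    row_slice: tuple[int, int]         # half-open raster-row bounds
    col_slice: tuple[int, int]
    centroid: tuple[float, float]      # map coordinates of the block center
    zone: int                          # majority zone of in-park cells
    area_km2: float                    # A_k: in-park cell count x cell area
    class_areas: dict[int, float] = field(default_factory=dict)  # A_ki
    flagged: bool = False              # sliver unit, excluded from sampling


@dataclass
class AssessmentGrid:
    units: list[AssessmentUnit]
    unit_size_m: float
    raster_cell_size: float

    def __iter__(self):
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def in_zone(self, zone: int) -> list[AssessmentUnit]:
        return [u for u in self.units if u.zone == zone]

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: one row per unit, A_ki as ``area_c<code>`` columns."""
        codes = sorted({c for u in self.units for c in u.class_areas})
        rows = []
        for u in self.units:
            row = {
                "row_block": u.unit_id[0],
                "col_block": u.unit_id[1],
                "x": u.centroid[0],
                "y": u.centroid[1],
                "zone": _ZONE_NAMES.get(u.zone, str(u.zone)),
                "A_k_km2": u.area_km2,
                "flagged": u.flagged,
            }
            for c in codes:
                row[f"area_c{c}"] = u.class_areas.get(c, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path, dtype=float) -> tuple[np.ndarray, float, tuple[float, float], float]:
    """Parse one ESRI ASCII grid; returns (values, cell_size, origin, nodata).

    The origin returned is the upper-left corner (the file stores the
    lower-left corner; rows in the file run north to south).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: empty or truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise ValueError(f"{path}: missing header keys {missing}")
        values = np.loadtxt(fh, dtype=dtype, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: body shape {values.shape} != header ({nrows}, {ncols})"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = header.get("nodata_value", -9999.0)
    return values, cell, origin, nodata


def write_raster(raster: LandUseRaster, path, fmt: str = "ascii") -> None:
    """Write a raster as an ESRI ASCII grid (bit-exact round-trip for codes).

    Integer arrays are written as integers, float arrays with full ``repr``
    precision.
    """
    if fmt != "ascii":
        raise ValueError(f"unsupported raster format {fmt!r} (only 'ascii')")
    arr = raster.values
    if arr.size == 0:
        raise ValueError("refusing to write an empty raster")
    nrows, ncols = arr.shape
    x0, y0 = raster.origin
    yll = y0 - nrows * raster.cell_size
    is_int = np.issubdtype(arr.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {int(raster.nodata) if is_int else raster.nodata!r}\n")
        for row in arr:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row))
            else:
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_landuse(path, catalog, unknown_tolerance: float = 0.0) -> LandUseRaster:
    """Read and validate a categorical land-use raster (ESRI ASCII grid).

    Codes absent from ``catalog`` are counted; if their fraction of non-nodata
    cells exceeds ``unknown_tolerance`` the read fails, listing each unknown
    code with its count.
    """
    values, cell, origin, nodata = read_ascii_grid(path, dtype=np.int64)
    raster = LandUseRaster(values, cell, origin, nodata=int(nodata))
    known = set(catalog.codes)
    data = values[values != raster.nodata]
    unknown_codes, counts = np.unique(
        data[~np.isin(data, list(known))], return_counts=True
    )
    if unknown_codes.size:
        frac = counts.sum() / max(data.size, 1)
        if frac > unknown_tolerance:
            listing = {int(c): int(n) for c, n in zip(unknown_codes, counts)}
            raise ValueError(
                f"{path}: {counts.sum()} cells ({100 * frac:.2f}%) carry codes "
                f"absent from the catalog: {listing}"
            )
    return raster


def read_zone_mask(path, companion: LandUseRaster | None = None) -> ZoneMask:
    """Read a core/general/outside mask; checks alignment with a companion raster."""
    values, cell, origin, nodata = read_ascii_grid(path, dtype=np.int64)
    bad = set(np.unique(values)) - {OUTSIDE, CORE, GENERAL}
    if bad:
        raise ValueError(f"{path}: mask contains non-zone codes {sorted(bad)}")
    mask = ZoneMask(values, cell, origin, nodata=int(nodata))
    if companion is not None:
        if mask.shape != companion.shape or mask.cell_size != companion.cell_size:
            raise ValueError(
                f"{path}: mask grid {mask.shape}@{mask.cell_size} m does not "
                f"match raster {companion.shape}@{companion.cell_size} m"
            )
    return mask


# ---------------------------------------------------------------------------
# Tessellation into assessment units


def tessellate(
    raster: LandUseRaster,
    mask: ZoneMask,
    cell_size_m: float = 400.0,
    min_area_fraction: float = 0.25,
) -> AssessmentGrid:
    """Tile the park footprint with square assessment units.

    Units are ``cell_size_m`` x ``cell_size_m`` blocks anchored at the raster
    origin. Units wholly outside the park are dropped; boundary units are kept
    with their reduced in-park area ``A_k``. Units with
    ``A_k < min_area_fraction x full unit area`` are flagged (excluded from
    interpolation sampling downstream, but still zoned).
    """
    if mask.shape != raster.shape:
        raise ValueError("mask and raster shapes differ")
    ratio = cell_size_m / raster.cell_size
    k = round(ratio)
    if k < 1 or abs(ratio - k) > 1e-9:
        near = max(1, k) * raster.cell_size
        raise ValueError(
            f"unit size {cell_size_m} m is not a positive multiple of the "
            f"raster resolution {raster.cell_size} m; nearest valid value is "
            f"{near} m"
        )
    nrows, ncols = raster.shape
    cell_area = raster.cell_area_km2
    full_area = cell_area * k * k
    zones = mask.values
    units: list[AssessmentUnit] = []
    for rb in range(math.ceil(nrows / k)):
        r0, r1 = rb * k, min((rb + 1) * k, nrows)
        for cb in range(math.ceil(ncols / k)):
            c0, c1 = cb * k, min((cb + 1) * k, ncols)
            zblock = zones[r0:r1, c0:c1]
            n_core = int(np.count_nonzero(zblock == CORE))
            n_general = int(np.count_nonzero(zblock == GENERAL))
            n_park = n_core + n_general
            if n_park == 0:
                continue
            zone = CORE if n_core >= n_general else GENERAL
            x0, y0 = raster.origin
            centroid = (
                x0 + (cb + 0.5) * cell_size_m,
                y0 - (rb + 0.5) * cell_size_m,
            )
            a_k = n_park * cell_area
            units.append(AssessmentUnit(
                unit_id=(rb, cb),
                row_slice=(r0, r1),
                col_slice=(c0, c1),
                centroid=centroid,
                zone=zone,
                area_km2=a_k,
                flagged=a_k < min_area_fraction * full_area,
            ))
    return AssessmentGrid(units, cell_size_m, raster.cell_size)


def unit_composition(
    grid: AssessmentGrid, raster: LandUseRaster, mask: ZoneMask
) -> AssessmentGrid:
    """Fill each unit's per-class in-park areas ``A_ki`` (km², exact counts x area).

    Nodata cells contribute to ``A_k`` (they are in the park) but to no class,
    so ``sum_i A_ki <= A_k`` with equality on nodata-free units.
    """
    cell_area = raster.cell_area_km2
    vals, zones = raster.values, mask.values
    for u in grid.units:
        r0, r1 = u.row_slice
        c0, c1 = u.col_slice
        block = vals[r0:r1, c0:c1]
        inpark = zones[r0:r1, c0:c1] != OUTSIDE
        data = block[inpark & (block != raster.nodata)]
        codes, counts = np.unique(data, return_counts=True)
        u.class_areas = {int(c): int(n) * cell_area for c, n in zip(codes, counts)}
    return grid
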