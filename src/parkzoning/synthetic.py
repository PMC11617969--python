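"""Synthetic land-use rasters and park masks for testing and demonstration.

The real input of the analysis — a supervised-classification land-use raster
of a national park — is not redistributable, so this module generates rasters
with the statistical structure the analysis assumes:

* a forest-dominated, spatially clumped 12-class mosaic, produced by the
  modified-random-clusters neutral landscape algorithm (Bernoulli site
  percolation, component clustering, cluster-to-class assignment by target
  proportions, nearest-cluster fill) — its clumping parameter controls exactly
  the fragmentation the risk index responds to;
* a contiguous park footprint with a contiguous core protected area
  (~52% of the park by default) surrounded by the general control area;
* fragmentation hot-spots (cultivated / garden / bare patches) near the
  core–general border and water/wetland pockets in the general area, the
  features the source maps localize high risk and high service value on.

Everything is deterministic per seed. A registry of hand-sized fixtures with
hand-computed expectations backs the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import CORE, GENERAL, OUTSIDE, LandUseRaster, ZoneMask

__all__ = [
    "HotspotSpec",
    "SyntheticParams",
    "generate_landscape",
    "generate_park_masks",
    "apply_hotspots",
    "simulate",
    "fixture_raster",
    "FIXTURES",
]

#: Forest-dominated default class proportions over the 12-code legend.
DEFAULT_PROPORTIONS: dict[int, float] = {
    2: 0.62,   # arbor forest
    3: 0.08,   # bamboo forest
    4: 0.06,   # shrubland
    5: 0.04,   # other forest
    6: 0.03,   # garden plot
    7: 0.04,   # grassland
    8: 0.03,   # non-irrigated field
    9: 0.03,   # irrigated field
    10: 0.02,  # wetland
    11: 0.02,  # water
    1: 0.015,  # building land
    12: 0.015, # bare land
}


@dataclass(frozen=True)
class HotspotSpec:
    """Clustered pockets of given classes, sprinkled at chosen locations."""

    count: int
    radius: int
    classes: tuple[int, ...]
    fill_prob: float = 0.45  # per-cell occupancy inside the radius


@dataclass
class SyntheticParams:
    n_rows: int = 260
    n_cols: int = 260
    cell_size: float = 100.0
    proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    clumping: float = 0.45          # site-percolation marking probability
    core_fraction: float = 0.5182   # core share of the park footprint
    border_hotspots: HotspotSpec = HotspotSpec(6, 4, (9, 6, 12))
    water_pockets: HotspotSpec = HotspotSpec(3, 3, (11, 10), fill_prob=0.85)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if not 0.0 <= self.clumping < 1.0:
            raise ValueError("clumping must be in [0, 1)")
        if not 0.0 < self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in (0, 1)")


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def generate_landscape(params: SyntheticParams) -> LandUseRaster:
    """Modified-random-clusters raster with the requested class proportions.

    With ``clumping = 0`` cells are independent multinomial draws; otherwise
    marked cells (Bernoulli ``p = clumping``) are clustered by 4-connectivity,
    each cluster drawn to a class with probability equal to its target
    proportion, and unmarked cells inherit the class of the nearest marked
    cell. Realized proportions track the targets; spatial clumping (mean patch
    size) grows with ``p``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = (params.n_rows, params.n_cols)
    codes = np.array(sorted(params.proportions))
    probs = np.array([params.proportions[c] for c in codes])
    probs = probs / probs.sum()
    if params.clumping == 0.0:
        values = rng.choice(codes, size=shape, p=probs)
        return LandUseRaster(values.astype(np.int64), params.cell_size)
    marked = rng.random(shape) < params.clumping
    if not marked.any():
        marked[tuple(rng.integers(0, s) for s in shape)] = True
    labels, n = ndimage.label(marked, structure=_STRUCT4)
    cluster_codes = rng.choice(codes, size=n + 1, p=probs)
    values = cluster_codes[labels]
    # nearest-cluster fill of unmarked cells
    idx = ndimage.distance_transform_edt(~marked, return_distances=False,
                                         return_indices=True)
    values = values[idx[0], idx[1]] if (~marked).any() else values
    values[marked] = cluster_codes[labels[marked]]
    return LandUseRaster(values.astype(np.int64), params.cell_size)


def generate_park_masks(
    raster: LandUseRaster,
    core_fraction: float = 0.5182,
    seed: int | None = 0,
    fraction_tol: float = 0.01,
) -> ZoneMask:
    """Contiguous park footprint with a contiguous core of the requested share.

    The footprint is a mildly perturbed ellipse inside the raster; the core is
    the distance-to-boundary superlevel set whose cell share of the park is
    within ``fraction_tol`` of ``core_fraction``, so the general control area
    forms a buffer fully surrounding the core.
    """
    if not 0.0 < core_fraction < 1.0:
        raise ValueError("core_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    nr, nc = raster.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    dy, dx = (rr - cy) / (0.42 * nr), (cc - cx) / (0.42 * nc)
    theta = np.arctan2(dy, dx)
    phi1, phi2 = rng.uniform(0, 2 * np.pi, 2)
    wobble = 1.0 + 0.08 * np.sin(3 * theta + phi1) + 0.05 * np.sin(5 * theta + phi2)
    park = (dx**2 + dy**2) <= wobble**2
    n_park = int(park.sum())
    if n_park < 16:
        raise ValueError("raster too small for a park footprint")
    dist = ndimage.distance_transform_edt(park)
    inside = dist[park]
    lo, hi = 0.0, float(inside.max())
    if hi <= 1.0:
        raise ValueError("park footprint too thin for a surrounded core")
    core = None
    for _ in range(60):  # bisect the distance threshold to hit the target share
        t = 0.5 * (lo + hi)
        cand = park & (dist >= t)
        # keep the largest 8-connected component so the core stays contiguous
        labels, n = ndimage.label(cand, structure=np.ones((3, 3), bool))
        if n > 1:
            sizes = np.bincount(labels.ravel())[1:]
            cand = labels == (1 + int(np.argmax(sizes)))
        frac = cand.sum() / n_park
        if abs(frac - core_fraction) <= fraction_tol:
            core = cand
            break
        if frac > core_fraction:
            lo = t
        else:
            hi = t
    if core is None:
        raise ValueError(
            f"cannot realize core_fraction={core_fraction} within "
            f"{fraction_tol:.0%} on this footprint"
        )
    values = np.full(raster.shape, OUTSIDE, dtype=np.int64)
    values[park] = GENERAL
    values[core] = CORE
    return ZoneMask(values, raster.cell_size, raster.origin)


def apply_hotspots(
    raster: LandUseRaster,
    mask: ZoneMask,
    border_hotspots: HotspotSpec | None,
    water_pockets: HotspotSpec | None,
    seed: int | None = 0,
) -> LandUseRaster:
    """Overlay fragmentation hot-spots and water/wetland pockets (new raster).

    Border hot-spots scatter the given classes as broken patches around
    randomly chosen core–general border cells; water pockets fill small
    near-solid disks inside the general area.
    """
    rng = np.random.default_rng(seed)
    values = raster.values.copy()
    zones = mask.values
    park = zones != OUTSIDE
    core = zones == CORE
    border = park & ndimage.binary_dilation(core, np.ones((3, 3), bool)) & ~core
    border |= core & ndimage.binary_dilation(~core & park, np.ones((3, 3), bool))

    def scatter(spec: HotspotSpec, candidates: np.ndarray) -> None:
        coords = np.argwhere(candidates)
        if len(coords) == 0 or spec.count == 0:
            return
        centers = coords[rng.choice(len(coords), size=min(spec.count, len(coords)),
                                    replace=False)]
        rr, cc = np.mgrid[-spec.radius:spec.radius + 1, -spec.radius:spec.radius + 1]
        disk = (rr**2 + cc**2) <= spec.radius**2
        offs = np.argwhere(disk) - spec.radius
        for cr, ccol in centers:
            cells = offs + (cr, ccol)
            ok = (
                (cells[:, 0] >= 0) & (cells[:, 0] < values.shape[0])
                & (cells[:, 1] >= 0) & (cells[:, 1] < values.shape[1])
            )
            cells = cells[ok]
            cells = cells[park[cells[:, 0], cells[:, 1]]]
            hit = rng.random(len(cells)) < spec.fill_prob
            cls = rng.choice(spec.classes, size=int(hit.sum()))
            values[cells[hit, 0], cells[hit, 1]] = cls
    if border_hotspots is not None:
        scatter(border_hotspots, border)
    if water_pockets is not None:
        interior_general = (zones == GENERAL) & ~border
        scatter(water_pockets, interior_general)
    return LandUseRaster(values, raster.cell_size, raster.origin,
                         raster.crs_tag, raster.nodata)


def simulate(params: SyntheticParams) -> tuple[LandUseRaster, ZoneMask]:
    """Full synthetic scene: clumped mosaic, park/core masks, hot-spots."""
    raster = generate_landscape(params)
    mask = generate_park_masks(raster, params.core_fraction, seed=params.seed + 1)
    raster = apply_hotspots(raster, mask, params.border_hotspots,
                            params.water_pockets, seed=params.seed + 2)
    return raster, mask


# ---------------------------------------------------------------------------
# Hand-checkable fixtures


def _fixture_single_class():
    # one 2x2 patch of arbor forest at 1 km cells: A = A_i = 4 km², n = 1
    values = np.full((2, 2), 2, dtype=np.int64)
    raster = LandUseRaster(values, 1000.0)
    mask = ZoneMask(np.full((2, 2), CORE, dtype=np.int64), 1000.0)
    expected = {
        "C_i": 0.25, "N_i": 0.25, "D_i": 1.0,
        "S_i": 0.6 * 0.25 + 0.3 * 0.25 + 0.1 * 1.0,  # 0.325
        "R_i_normalized": (2 / 78) * 0.325,
    }
    return raster, mask, expected


def _fixture_diag_pair():
    # two bare-land cells touching only diagonally on a forest background
    values = np.full((3, 3), 2, dtype=np.int64)
    values[0, 0] = values[1, 1] = 12
    raster = LandUseRaster(values, 100.0)
    mask = ZoneMask(np.full((3, 3), CORE, dtype=np.int64), 100.0)
    return raster, mask, {"n_patches_conn8": 1, "n_patches_conn4": 2}


def _fixture_water_pocket():
    # 8x8 at 100 m -> four 400 m units, all GENERAL; unit (0, 0) holds water
    values = np.full((8, 8), 2, dtype=np.int64)
    values[1:3, 1:3] = 11
    raster = LandUseRaster(values, 100.0)
    mask = ZoneMask(np.full((8, 8), GENERAL, dtype=np.int64), 100.0)
    return raster, mask, {"highest_esv_unit": (0, 0)}


FIXTURES = {
    "single-class-4km2": _fixture_single_class,
    "diag-pair": _fixture_diag_pair,
    "water-pocket": _fixture_water_pocket,
}


def fixture_raster(name: str):
    """Return ``(raster, mask, expected)`` for a registered fixture."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return builder()
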