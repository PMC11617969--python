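"""Per-class landscape pattern metrics: fragmentation, isolation, dominance, disturbance.

For each land-use class *i* inside one analysis region (a masked part of the
raster, typically the core protected area) with total area *A*:

* fragmentation  ``C_i = n_i / A_i``            (patches per km²)
* isolation      ``N_i = (A / (2 A_i)) * sqrt(n_i / A)``
* dominance      ``D_i = (M_i + L_i) / 2`` with patch-number share
  ``M_i = n_i / sum_j n_j`` and area share ``L_i = A_i / A``
* disturbance    ``S_i = a C_i + b N_i + c D_i``  with weights
  ``(a, b, c) = (0.6, 0.3, 0.1)`` by default.

Patch counts ``n_i`` come from connected-component labeling (8-connectivity by
default, the FRAGSTATS convention; 4-connectivity available). Nodata and
out-of-region cells break connectivity.

The default scope is landscape-global: all of ``n_i, A_i, M_i, L_i, A`` are
taken over the whole region, so the disturbance (and downstream loss) index is
one number per class; per-assessment-unit variation then enters only through
land-use composition. Optionally the metrics can be recomputed inside each
unit's window instead (``scope="per-unit"`` in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PatchLabeling", "ClassMetricsTable", "label_patches", "class_metrics"]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}

DEFAULT_WEIGHTS = (0.6, 0.3, 0.1)


@dataclass
class PatchLabeling:
    class_code: int
    n_patches: int
    patch_cells: np.ndarray  # cell count per patch, length n_patches
    connectivity: int

    @property
    def total_cells(self) -> int:
        return int(self.patch_cells.sum())


@dataclass
class ClassMetricsTable:
    """One row per occurring class; ``landscape_area_km2`` is *A*."""

    table: pd.DataFrame  # index: class code; columns n_i, A_i_km2, M_i, L_i, C_i, N_i, D_i, S_i
    landscape_area_km2: float
    weights: tuple[float, float, float]
    connectivity: int

    def s_index(self) -> dict[int, float]:
        return self.table["S_i"].to_dict()

    def __getitem__(self, code: int) -> pd.Series:
        return self.table.loc[code]


def label_patches(
    raster, region_mask: np.ndarray, class_code: int, connectivity: int = 8
) -> PatchLabeling:
    """Connected components of ``class_code`` cells within the region.

    ``region_mask`` is a boolean array on the raster grid; cells outside it
    (and nodata cells) are background and break connectivity. An absent class
    yields ``n_patches = 0``.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    target = (raster.values == class_code) & region_mask
    labels, n = ndimage.label(target, structure=_STRUCTURES[connectivity])
    if n == 0:
        counts = np.zeros(0, dtype=np.int64)
    else:
        counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return PatchLabeling(class_code, int(n), counts, connectivity)


def class_metrics(
    raster,
    region_mask: np.ndarray,
    catalog,
    connectivity: int = 8,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> ClassMetricsTable:
    """Compute the per-class metric table over one region.

    Only classes occurring in the region get a row. Raises on an empty region.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != raster.shape:
        raise ValueError("region mask shape does not match the raster")
    cell_area = raster.cell_area_km2
    inside = raster.values[region_mask]
    inside = inside[inside != raster.nodata]
    if inside.size == 0:
        raise ValueError("analysis region is empty (no data cells)")
    A = inside.size * cell_area

    known = set(catalog.codes)
    occurring = [int(c) for c in np.unique(inside)]
    stray = [c for c in occurring if c not in known]
    if stray:
        raise ValueError(f"classes {stray} occur in the region but not in the catalog")

    rows = []
    n_total = 0
    labelings = {}
    for code in occurring:
        lab = label_patches(raster, region_mask, code, connectivity)
        labelings[code] = lab
        n_total += lab.n_patches
    a, b, c = weights
    for code in occurring:
        lab = labelings[code]
        n_i = lab.n_patches
        A_i = lab.total_cells * cell_area
        C_i = n_i / A_i
        N_i = (A / (2.0 * A_i)) * np.sqrt(n_i / A)
        M_i = n_i / n_total
        L_i = A_i / A
        D_i = 0.5 * (M_i + L_i)
        S_i = a * C_i + b * N_i + c * D_i
        rows.append({
            "code": code, "n_i": n_i, "A_i_km2": A_i, "M_i": M_i, "L_i": L_i,
            "C_i": C_i, "N_i": N_i, "D_i": D_i, "S_i": S_i,
        })
    table = pd.DataFrame(rows).set_index("code")
    return ClassMetricsTable(table, A, weights, connectivity)
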