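"""Ordinary kriging of unit-centroid values onto a zone surface.

Three stages, each usable on its own:

1. :func:`empirical_semivariogram` — method-of-moments estimate
   ``γ̂(h) = mean of ½ (v_a − v_b)²`` over point pairs binned by separation;
2. :func:`fit_variogram` — weighted least squares (weights = pair counts) fit
   of a spherical / exponential / gaussian model with a deterministic
   multi-start over range initializations;
3. :func:`krige` — local-neighborhood ordinary kriging: per target, the
   nearest ``neighborhood`` samples enter the OK system with the unbiasedness
   constraint (weights sum to 1).

Exponential and gaussian families use the practical-range convention
(γ reaches ~95% of the sill at the stated range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = [
    "VariogramModel",
    "Surface",
    "empirical_semivariogram",
    "fit_variogram",
    "krige",
    "krige_points",
]

_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class VariogramModel:
    family: str
    nugget: float
    partial_sill: float
    range_: float

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters out of bounds")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h) -> np.ndarray:
        """γ(h); γ(0) = 0 exactly (the nugget is a discontinuity at the origin)."""
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "spherical":
            x = np.clip(h / r, 0.0, 1.0)
            structured = self.partial_sill * (1.5 * x - 0.5 * x**3)
        elif self.family == "exponential":
            structured = self.partial_sill * (1.0 - np.exp(-3.0 * h / r))
        else:  # gaussian
            structured = self.partial_sill * (1.0 - np.exp(-3.0 * (h / r) ** 2))
        return np.where(h > 0, self.nugget + structured, 0.0)


@dataclass
class Surface:
    """Interpolated values on the coarse (assessment-unit) grid of one zone."""

    values: np.ndarray            # float raster, NaN outside the zone
    cell_size: float              # meters (the unit size)
    origin: tuple[float, float]
    kind: str                     # "ERI" / "ESV"
    variogram: VariogramModel
    n_samples: int
    nodata: float = float("nan")


def empirical_semivariogram(
    samples: np.ndarray, n_lags: int = 12, max_lag: float | None = None
) -> np.ndarray:
    """Binned semivariogram of ``samples`` given as (x, y, value) rows.

    Returns rows ``(lag_center, gamma_hat, n_pairs)``; empty bins are dropped.
    ``max_lag`` defaults to half the sample-cloud diameter.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be (n, 3): x, y, value")
    if len(samples) < 10:
        raise ValueError("need at least 10 samples for a semivariogram")
    xy, v = samples[:, :2], samples[:, 2]
    d = pdist(xy)
    if d.max() == 0:
        raise ValueError("all samples are coincident")
    if max_lag is None:
        max_lag = 0.5 * d.max()
    dv = 0.5 * pdist(v[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= max_lag
    rows = []
    for b in range(n_lags):
        sel = keep & (which == b)
        n = int(np.count_nonzero(sel))
        if n == 0:
            continue
        rows.append((0.5 * (edges[b] + edges[b + 1]), float(dv[sel].mean()), n))
    return np.array(rows, dtype=float).reshape(-1, 3)


def fit_variogram(empirical: np.ndarray, family: str = "spherical") -> VariogramModel:
    """WLS fit of (nugget, partial sill, range) to a binned semivariogram.

    Pair counts weight the residuals. The optimizer is bounded and started
    from a fixed ladder of range guesses, so the fit is deterministic. A
    degenerate outcome falls back to a pure-nugget model with a warning.
    """
    empirical = np.asarray(empirical, dtype=float).reshape(-1, 3)
    if len(empirical) < 3:
        raise ValueError("need at least 3 nonempty semivariogram bins")
    lags, gam, cnt = empirical.T
    w = np.sqrt(cnt)
    gmax = gam.max()
    hmax = lags.max()
    mean_g = float(np.average(gam, weights=cnt))

    if gmax == 0:  # constant field
        warnings.warn("flat zero semivariogram; falling back to pure nugget")
        return VariogramModel(family, 0.0, 0.0, hmax)

    def resid(theta):
        m = VariogramModel(family, theta[0], theta[1], theta[2])
        return w * (m(lags) - gam)

    lo = [0.0, 0.0, 1e-9 * hmax]
    hi = [2.0 * gmax, 4.0 * gmax, 4.0 * hmax]
    best, best_cost = None, np.inf
    for frac in (0.2, 0.5, 1.0, 2.0):
        x0 = [max(min(gam.min(), gmax), 0.0), max(gmax - gam.min(), 1e-12 * gmax),
              frac * hmax]
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res.x, res.cost
    if best is None:
        warnings.warn("variogram fit failed; falling back to pure nugget")
        return VariogramModel(family, mean_g, 0.0, hmax)
    nugget, psill, rng = best
    return VariogramModel(family, float(nugget), float(psill), float(rng))


def _solve_ok(xy_nb: np.ndarray, v_nb: np.ndarray, x0: np.ndarray,
              model: VariogramModel) -> tuple[float, np.ndarray]:
    """Solve one ordinary-kriging system; returns (prediction, weights)."""
    m = len(xy_nb)
    diff = xy_nb[:, None, :] - xy_nb[None, :, :]
    G = model(np.sqrt((diff**2).sum(-1)))
    A = np.empty((m + 1, m + 1))
    A[:m, :m] = G
    A[m, :m] = A[:m, m] = 1.0
    A[m, m] = 0.0
    b = np.empty(m + 1)
    b[:m] = model(np.sqrt(((xy_nb - x0) ** 2).sum(-1)))
    b[m] = 1.0
    sol = np.linalg.solve(A, b)
    lam = sol[:m]
    return float(lam @ v_nb), lam


def krige_points(
    samples: np.ndarray,
    model: VariogramModel,
    points: np.ndarray,
    neighborhood: int = 16,
    return_weights: bool = False,
):
    """Ordinary-kriging predictions at arbitrary ``points`` (n, 2).

    Per point the nearest ``neighborhood`` samples form the OK system. A
    singular system first retries with all samples, then falls back to
    inverse-distance weighting with a warning.
    """
    samples = np.asarray(samples, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    xy, v = samples[:, :2], samples[:, 2]
    if len(np.unique(xy, axis=0)) < len(xy):
        raise ValueError("coincident sample locations")
    k = min(neighborhood, len(xy))
    tree = cKDTree(xy)
    preds = np.empty(len(points))
    weights = [] if return_weights else None
    for j, p in enumerate(points):
        _, idx = tree.query(p, k=k)
        idx = np.atleast_1d(idx)
        try:
            pred, lam = _solve_ok(xy[idx], v[idx], p, model)
            if not np.isfinite(pred):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            try:
                pred, lam = _solve_ok(xy, v, p, model)
                idx = np.arange(len(xy))
            except np.linalg.LinAlgError:
                warnings.warn("singular kriging system; using inverse-distance weights")
                d = np.sqrt(((xy[idx] - p) ** 2).sum(-1))
                if np.any(d == 0):
                    lam = (d == 0) / np.count_nonzero(d == 0)
                else:
                    lam = (1.0 / d**2) / (1.0 / d**2).sum()
                pred = float(lam @ v[idx])
        preds[j] = pred
        if return_weights:
            weights.append((idx, lam))
    if return_weights:
        return preds, weights
    return preds


def krige(
    samples: np.ndarray,
    model: VariogramModel,
    target_grid,
    zone: int,
    neighborhood: int = 16,
    kind: str = "",
) -> Surface:
    """Krige a field onto every assessment unit of one zone.

    ``target_grid`` is an :class:`~parkzoning.raster.AssessmentGrid`; the
    returned :class:`Surface` is a coarse float raster (one cell per unit,
    NaN outside the zone) so grading and zoning can operate per cell.
    """
    units = target_grid.in_zone(zone)
    if not units:
        raise ValueError("no units in the target zone")
    nrb = max(u.unit_id[0] for u in target_grid.units) + 1
    ncb = max(u.unit_id[1] for u in target_grid.units) + 1
    values = np.full((nrb, ncb), np.nan)
    pts = np.array([u.centroid for u in units])
    preds = krige_points(samples, model, pts, neighborhood)
    for u, p in zip(units, preds):
        values[u.unit_id] = p
    # the coarse grid shares the raster origin; its cell size is the unit size
    any_u = target_grid.units[0]
    x0 = any_u.centroid[0] - (any_u.unit_id[1] + 0.5) * target_grid.unit_size_m
    y0 = any_u.centroid[1] + (any_u.unit_id[0] + 0.5) * target_grid.unit_size_m
    return Surface(values, target_grid.unit_size_m, (x0, y0), kind, model,
                   n_samples=len(samples))
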