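"""End-to-end orchestration: config, the ZoningModel / ZoningResults pair, outputs.

The model object binds the inputs (land-use raster, park mask, class catalog,
resolved configuration); ``fit()`` runs the full analysis —

    tessellation -> per-unit composition -> per-class metrics & loss indices
    -> ERI field over the core area and ESV field over the general area
    -> semivariogram fit and ordinary kriging of each field onto its zone
    -> Jenks 5-grade maps -> CHR/CLR/GHE/GLE synthesis -> area & value reports

— and returns a results object carrying every intermediate product, a
``summary()`` table and ``plot()``/``save()`` helpers. All open numeric
choices (weights, connectivity, normalization, variogram family, neighborhood,
break count, cuts) live in the config and are echoed into the resolved config
dump next to the outputs, so a run is auditable and reproducible from its
output directory alone.
"""

from __future__ import annotations

import copy
import difflib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import classify as zc
from .catalog import ClassCatalog, default_catalog, load_catalog, save_catalog
from .classify import BreakSet, GradeMap, ZoneReport, ZoningMap
from .eri import LossIndexTable, ScalarField, eri_field
from .esv import ServiceValueReport, esv_field, service_report
from .kriging import Surface, empirical_semivariogram, fit_variogram, krige
from .raster import (CORE, GENERAL, AssessmentGrid, LandUseRaster, ZoneMask,
                     read_landuse, read_zone_mask, tessellate,
                     unit_composition, write_raster)
from .synthetic import SyntheticParams, simulate

__all__ = ["PipelineConfig", "load_config", "ZoningModel", "ZoningResults",
           "run_pipeline", "DEFAULTS"]

logger = logging.getLogger("parkzoning")

DEFAULTS: dict = {
    "inputs": {"landuse": None, "mask": None, "catalog": None},
    "synthetic": {
        "enabled": True,
        "n_rows": 260, "n_cols": 260, "cell_size": 100.0,
        "clumping": 0.45, "core_fraction": 0.5182,
    },
    "grid": {"cell_size_m": 400.0, "min_area_fraction": 0.25},
    "metrics": {
        "connectivity": 8,
        "weights": [0.6, 0.3, 0.1],
        "scope": "landscape-global",
    },
    "eri": {"normalize_F": True},
    "variogram": {"family": "spherical", "n_lags": 12, "max_lag": None},
    "kriging": {"neighborhood": 16},
    "breaks": {"k": 5},
    "zoning": {"eri_cut": None, "esv_cut": None},
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated, fully-resolved configuration (defaults filled in)."""

    data: dict

    def __getitem__(self, key):
        return self.data[key]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)


def _merge(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in given.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            hint = difflib.get_close_matches(str(key), list(defaults), n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {here!r}{extra}")
        if isinstance(defaults[key], dict) and not isinstance(val, dict) and val is not None:
            raise ValueError(f"config key {here!r} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], val or {}, here)
        else:
            out[key] = val
    return out


def load_config(source=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config file (or mapping), fill defaults, reject unknown keys.

    ``overrides`` is a second mapping merged on top (CLI flags). A weights
    vector not summing to 1 is accepted with a warning.
    """
    given: dict = {}
    if source is not None:
        if isinstance(source, dict):
            given = source
        else:
            with open(source) as fh:
                given = yaml.safe_load(fh) or {}
            if not isinstance(given, dict):
                raise ValueError(f"{source}: config must be a mapping")
    data = _merge(DEFAULTS, given)
    if overrides:
        data = _merge(data, overrides)
    w = data["metrics"]["weights"]
    if len(w) != 3 or any(x < 0 for x in w):
        raise ValueError("metrics.weights must be three non-negative numbers")
    if abs(sum(w) - 1.0) > 1e-9:
        logger.warning("disturbance weights %s do not sum to 1", w)
    if data["metrics"]["connectivity"] not in (4, 8):
        raise ValueError("metrics.connectivity must be 4 or 8")
    if data["breaks"]["k"] < 1:
        raise ValueError("breaks.k must be >= 1")
    return PipelineConfig(data)


@dataclass
class ZoningResults:
    """Everything one fitted run produces; returned by :meth:`ZoningModel.fit`."""

    model: "ZoningModel"
    grid: AssessmentGrid
    eri: ScalarField | None
    loss: LossIndexTable | None
    esv: ScalarField | None
    eri_surface: Surface | None
    esv_surface: Surface | None
    eri_breaks: BreakSet | None
    esv_breaks: BreakSet | None
    eri_grades: GradeMap | None
    esv_grades: GradeMap | None
    zoning: ZoningMap
    zone_report: ZoneReport
    services: ServiceValueReport | None
    timings: dict[str, float]

    def summary(self) -> str:
        cfg = self.model.config.data
        lines = []
        push = lines.append
        push("Risk-value park zoning results")
        push("=" * 34)
        push(f"assessment units: {len(self.grid)} "
             f"({len(self.grid.in_zone(CORE))} core, "
             f"{len(self.grid.in_zone(GENERAL))} general) "
             f"at {self.grid.unit_size_m:g} m")
        push(f"park area: {self.zone_report.park_area_km2:.2f} km2")
        push(f"weights (a,b,c): {tuple(cfg['metrics']['weights'])}, "
             f"connectivity {cfg['metrics']['connectivity']}, "
             f"normalize_F {cfg['eri']['normalize_F']}")
        for name, surf, brks in (("ERI", self.eri_surface, self.eri_breaks),
                                 ("ESV", self.esv_surface, self.esv_breaks)):
            if surf is None:
                push(f"{name}: skipped (zone absent)")
                continue
            vg = surf.variogram
            push(f"{name} variogram: {vg.family} nugget={vg.nugget:.4g} "
                 f"psill={vg.partial_sill:.4g} range={vg.range_:.4g} m "
                 f"({surf.n_samples} samples)")
            if brks is not None:
                push(f"{name} breaks: "
                     + ", ".join(f"{b:.4g}" for b in brks.breaks))
        push(f"cuts: ERI >= {self.zoning.eri_cut:.4g} -> CHR; "
             f"ESV >= {self.zoning.esv_cut:.4g} -> GHE")
        push("")
        push(self.zone_report.zones.to_string(index=False,
                                              float_format=lambda v: f"{v:.2f}"))
        if self.services is not None:
            push("")
            push(self.services.to_frame().to_string(index=False))
            push(f"total: {self.services.total:.2f} wanyuan "
                 f"({self.services.total_million_rmb:.2f} RMB million)")
        return "\n".join(lines)

    def plot(self, path=None):
        from .plotting import plot_results
        return plot_results(self, path)

    def save(self, outdir) -> None:
        """Write every product (CSV tables, ASCII rasters, resolved config)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.model.config.to_yaml(out / "config.resolved.yaml")
        self.grid.to_frame().to_csv(out / "assessment_grid.csv", index=False)
        if self.loss is not None:
            self.loss.table.to_csv(out / "loss_index.csv")
        for name, fld in (("eri_field", self.eri), ("esv_field", self.esv)):
            if fld is not None:
                fld.to_frame().to_csv(out / f"{name}.csv", index=False)
        for name, surf in (("eri_surface", self.eri_surface),
                           ("esv_surface", self.esv_surface)):
            if surf is not None:
                write_raster(
                    LandUseRaster(surf.values, surf.cell_size, surf.origin,
                                  nodata=-9999),
                    out / f"{name}.asc")
        zr = LandUseRaster(self.zoning.values, self.grid.unit_size_m,
                           self._surface_origin(), nodata=zc.NONE)
        write_raster(zr, out / "zoning.asc")
        self.zone_report.zones.to_csv(out / "zone_report.csv", index=False)
        if len(self.zone_report.grades):
            self.zone_report.grades.to_csv(out / "grade_report.csv", index=False)
        if self.services is not None:
            self.services.to_frame().to_csv(out / "service_report.csv", index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        with open(out / "timings.json", "w") as fh:
            json.dump(self.timings, fh, indent=2)

    def _surface_origin(self) -> tuple[float, float]:
        s = self.eri_surface or self.esv_surface
        return s.origin if s is not None else (0.0, 0.0)


class ZoningModel:
    """Risk-value zoning analysis bound to one raster, mask and catalog.

    Parameters
    ----------
    raster, mask : LandUseRaster, ZoneMask
        The categorical land-use grid and the core/general/outside partition.
    catalog : ClassCatalog, optional
        Legend, vulnerability ranks and valuation table (default legend used
        when omitted).
    config : PipelineConfig | dict | None
        Analysis settings; unknown keys are rejected.
    """

    def __init__(self, raster: LandUseRaster, mask: ZoneMask,
                 catalog: ClassCatalog | None = None, config=None):
        self.raster = raster
        self.mask = mask
        self.catalog = catalog or default_catalog()
        self.config = config if isinstance(config, PipelineConfig) else load_config(config)

    @classmethod
    def from_synthetic(cls, config=None, catalog: ClassCatalog | None = None) -> "ZoningModel":
        """Build the model on a generated scene (see :mod:`parkzoning.synthetic`)."""
        cfg = config if isinstance(config, PipelineConfig) else load_config(config)
        s = cfg["synthetic"]
        params = SyntheticParams(
            n_rows=s["n_rows"], n_cols=s["n_cols"], cell_size=s["cell_size"],
            clumping=s["clumping"], core_fraction=s["core_fraction"],
            seed=cfg["seed"],
        )
        raster, mask = simulate(params)
        return cls(raster, mask, catalog, cfg)

    @classmethod
    def from_files(cls, landuse_path, mask_path, catalog_path=None, config=None) -> "ZoningModel":
        cfg = config if isinstance(config, PipelineConfig) else load_config(config)
        catalog = load_catalog(catalog_path) if catalog_path else default_catalog()
        raster = read_landuse(landuse_path, catalog)
        mask = read_zone_mask(mask_path, companion=raster)
        return cls(raster, mask, catalog, cfg)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> ZoningResults:
        cfg = self.config.data
        timings: dict[str, float] = {}
        current: list[str] = ["setup"]

        def stage(name):
            current[0] = name
            timings[name] = time.perf_counter()
            logger.info("stage %s", name)

        def done(name):
            timings[name] = time.perf_counter() - timings[name]

        try:
            stage("tessellate")
            grid = tessellate(self.raster, self.mask,
                              cfg["grid"]["cell_size_m"],
                              cfg["grid"]["min_area_fraction"])
            unit_composition(grid, self.raster, self.mask)
            done("tessellate")
            logger.info("%d assessment units (%d core, %d general)",
                        len(grid), len(grid.in_zone(CORE)),
                        len(grid.in_zone(GENERAL)))

            eri_fld = loss = esv_fld = None
            if grid.in_zone(CORE):
                stage("eri")
                eri_fld, loss = eri_field(
                    grid, self.raster, self.mask, self.catalog,
                    connectivity=cfg["metrics"]["connectivity"],
                    weights=tuple(cfg["metrics"]["weights"]),
                    normalize_F=cfg["eri"]["normalize_F"],
                    scope=cfg["metrics"]["scope"],
                )
                done("eri")
            else:
                logger.info("no core units: ERI stages skipped")
            if grid.in_zone(GENERAL):
                stage("esv")
                esv_fld = esv_field(grid, self.raster, self.mask, self.catalog)
                done("esv")
            else:
                logger.info("no general units: ESV stages skipped")
            if eri_fld is None and esv_fld is None:
                raise ValueError("park footprint is empty: nothing to assess")

            surfaces: dict[str, Surface | None] = {"ERI": None, "ESV": None}
            breaksets: dict[str, BreakSet | None] = {"ERI": None, "ESV": None}
            grades: dict[str, GradeMap | None] = {"ERI": None, "ESV": None}
            for fld, zone in ((eri_fld, CORE), (esv_fld, GENERAL)):
                if fld is None:
                    continue
                stage(f"krige_{fld.kind}")
                samples = fld.samples()
                if len(samples) < 10:
                    samples = fld.samples(include_flagged=True)
                emp = empirical_semivariogram(
                    samples, n_lags=cfg["variogram"]["n_lags"],
                    max_lag=cfg["variogram"]["max_lag"])
                model = fit_variogram(emp, cfg["variogram"]["family"])
                surf = krige(samples, model, grid, zone,
                             neighborhood=cfg["kriging"]["neighborhood"],
                             kind=fld.kind)
                surfaces[fld.kind] = surf
                done(f"krige_{fld.kind}")
                stage(f"grade_{fld.kind}")
                brk = zc.jenks_breaks(surf.values[~np.isnan(surf.values)],
                                      k=cfg["breaks"]["k"])
                breaksets[fld.kind] = brk
                grades[fld.kind] = zc.apply_grades(surf, brk)
                done(f"grade_{fld.kind}")

            stage("zone")
            zoning = self._zoning(grid, surfaces, breaksets, cfg)
            report = zc.zone_report(zoning, grid, grades["ERI"], grades["ESV"])
            services = service_report(esv_fld) if esv_fld is not None else None
            done("zone")
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed in stage {current[0]!r}: {exc}") from exc

        return ZoningResults(
            model=self, grid=grid, eri=eri_fld, loss=loss, esv=esv_fld,
            eri_surface=surfaces["ERI"], esv_surface=surfaces["ESV"],
            eri_breaks=breaksets["ERI"], esv_breaks=breaksets["ESV"],
            eri_grades=grades["ERI"], esv_grades=grades["ESV"],
            zoning=zoning, zone_report=report, services=services,
            timings=timings,
        )

    def _zoning(self, grid, surfaces, breaksets, cfg) -> ZoningMap:
        eri_cut = cfg["zoning"]["eri_cut"]
        esv_cut = cfg["zoning"]["esv_cut"]
        es, vs = surfaces["ERI"], surfaces["ESV"]
        if es is not None and vs is not None:
            return zc.four_zone_map(es, vs, grid,
                                    eri_breaks=breaksets["ERI"],
                                    esv_breaks=breaksets["ESV"],
                                    eri_cut=eri_cut, esv_cut=esv_cut)
        # one-sided park (degenerate but allowed): label only the present side
        surf = es or vs
        values = np.full(surf.values.shape, zc.NONE, dtype=int)
        if es is not None:
            cut = eri_cut if eri_cut is not None else breaksets["ERI"].breaks[0]
            for u in grid.in_zone(CORE):
                values[u.unit_id] = zc.CHR if es.values[u.unit_id] >= cut else zc.CLR
            return ZoningMap(values, float(cut), float("nan"))
        cut = esv_cut if esv_cut is not None else breaksets["ESV"].breaks[1]
        for u in grid.in_zone(GENERAL):
            values[u.unit_id] = zc.GHE if vs.values[u.unit_id] >= cut else zc.GLE
        return ZoningMap(values, float("nan"), float(cut))


def run_pipeline(config=None, outdir=None) -> ZoningResults:
    """Convenience wrapper: resolve config, build the model, fit, optionally save."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    if cfg["inputs"]["landuse"]:
        model = ZoningModel.from_files(cfg["inputs"]["landuse"],
                                       cfg["inputs"]["mask"],
                                       cfg["inputs"]["catalog"], cfg)
    else:
        model = ZoningModel.from_synthetic(cfg)
    results = model.fit()
    if outdir is not None:
        results.save(outdir)
        save_catalog(model.catalog, Path(outdir) / "catalog.yaml")
    return results
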