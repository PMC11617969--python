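"""Land-use legend, ecological vulnerability ranks and ecosystem-service coefficients.

The catalog couples three things that every downstream stage needs:

* the integer class codes of the categorical land-use raster and their names;
* the ecological vulnerability rank ``F_i`` of each class (rank 1 = least
  vulnerable, e.g. building land; rank 12 = most vulnerable, e.g. bare land);
* the regrouping of the 12 mapped classes into the 8 groups used by the
  equivalent-factor ecosystem-service valuation, together with the
  dimensionless equivalence factors per service subcategory and the monetary
  value of one equivalent (yuan per km² per year).

The per-class service coefficients ``VC_i`` follow as
``equivalents[group(i)][s] * unit_equivalent_value`` and are reported in
万元 (RMB 10⁴) per km².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SERVICE_CATEGORIES",
    "SERVICE_SUBCATEGORIES",
    "ESV_GROUPS",
    "LandUseClass",
    "ClassCatalog",
    "default_catalog",
    "validate_catalog",
    "coefficient_table",
    "load_catalog",
    "save_catalog",
]

#: The four top-level service categories and their subcategories, in report order.
SERVICE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "provisioning": ("food_production", "raw_materials", "water_supply"),
    "regulating": (
        "gas_regulation",
        "climate_regulation",
        "environment_purification",
        "hydrological_regulation",
    ),
    "supporting": ("soil_conservation", "nutrient_cycling", "biodiversity"),
    "cultural": ("aesthetic_landscape",),
}

SERVICE_SUBCATEGORIES: tuple[str, ...] = tuple(
    s for subs in SERVICE_CATEGORIES.values() for s in subs
)

#: The 8 valuation groups the 12 mapped classes collapse into.
ESV_GROUPS: tuple[str, ...] = (
    "forest land",
    "irrigated field",
    "non-irrigated field",
    "grassland",
    "wetland",
    "water",
    "building land",
    "bare land",
)


@dataclass(frozen=True)
class LandUseClass:
    """One land-use class of the legend.

    Parameters
    ----------
    code : int
        Raster class code, a small positive integer, unique in the catalog.
    name : str
        Human-readable label.
    vulnerability_rank : int
        Ecological vulnerability rank ``F_i`` in 1..12; larger = more
        vulnerable to disturbance.
    esv_group : str
        The valuation group this class maps to (one of :data:`ESV_GROUPS`).
    color : str | None
        Optional display tag; carried through, never interpreted.
    """

    code: int
    name: str
    vulnerability_rank: int
    esv_group: str
    color: str | None = None


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered legend plus the equivalent-factor valuation inputs.

    ``equivalents`` maps an esv group to a ``{subcategory: factor}`` mapping of
    dimensionless, non-negative equivalence factors. ``unit_equivalent_value``
    is the monetary value of one equivalent, in yuan per km² per year.
    """

    classes: tuple[LandUseClass, ...]
    unit_equivalent_value: float
    equivalents: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def by_code(self, code: int) -> LandUseClass:
        for c in self.classes:
            if c.code == code:
                return c
        raise KeyError(f"no land-use class with code {code}")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c.code for c in self.classes)

    def rank_sum(self) -> int:
        """Sum of vulnerability ranks, the normalizer for F̂_i."""
        return sum(c.vulnerability_rank for c in self.classes)


# Default per-unit-area equivalence factors, following the national
# equivalent-factor valuation literature (one row per esv group, columns are
# the 11 service subcategories). Building land carries zero equivalents by
# convention; the whole table is overridable from a catalog file.
_DEFAULT_EQUIVALENTS: dict[str, dict[str, float]] = {
    "forest land": {
        "food_production": 0.29, "raw_materials": 0.66, "water_supply": 0.34,
        "gas_regulation": 2.17, "climate_regulation": 6.50,
        "environment_purification": 1.93, "hydrological_regulation": 4.74,
        "soil_conservation": 2.65, "nutrient_cycling": 0.20,
        "biodiversity": 2.41, "aesthetic_landscape": 1.06,
    },
    "irrigated field": {
        "food_production": 1.36, "raw_materials": 0.09, "water_supply": 0.27,
        "gas_regulation": 1.11, "climate_regulation": 0.57,
        "environment_purification": 0.17, "hydrological_regulation": 2.72,
        "soil_conservation": 0.01, "nutrient_cycling": 0.19,
        "biodiversity": 0.21, "aesthetic_landscape": 0.09,
    },
    "non-irrigated field": {
        "food_production": 0.85, "raw_materials": 0.40, "water_supply": 0.02,
        "gas_regulation": 0.67, "climate_regulation": 0.36,
        "environment_purification": 0.10, "hydrological_regulation": 0.27,
        "soil_conservation": 1.03, "nutrient_cycling": 0.12,
        "biodiversity": 0.13, "aesthetic_landscape": 0.06,
    },
    "grassland": {
        "food_production": 0.38, "raw_materials": 0.56, "water_supply": 0.31,
        "gas_regulation": 1.97, "climate_regulation": 5.21,
        "environment_purification": 1.72, "hydrological_regulation": 3.82,
        "soil_conservation": 2.40, "nutrient_cycling": 0.18,
        "biodiversity": 2.18, "aesthetic_landscape": 0.96,
    },
    "wetland": {
        "food_production": 0.51, "raw_materials": 0.50, "water_supply": 2.59,
        "gas_regulation": 1.90, "climate_regulation": 3.60,
        "environment_purification": 3.60, "hydrological_regulation": 24.23,
        "soil_conservation": 2.31, "nutrient_cycling": 0.18,
        "biodiversity": 7.87, "aesthetic_landscape": 4.73,
    },
    "water": {
        "food_production": 0.80, "raw_materials": 0.23, "water_supply": 8.29,
        "gas_regulation": 0.77, "climate_regulation": 2.29,
        "environment_purification": 5.55, "hydrological_regulation": 102.24,
        "soil_conservation": 0.93, "nutrient_cycling": 0.07,
        "biodiversity": 2.55, "aesthetic_landscape": 1.89,
    },
    "building land": {s: 0.0 for s in SERVICE_SUBCATEGORIES},
    "bare land": {
        "food_production": 0.01, "raw_materials": 0.03, "water_supply": 0.02,
        "gas_regulation": 0.11, "climate_regulation": 0.10,
        "environment_purification": 0.31, "hydrological_regulation": 0.21,
        "soil_conservation": 0.13, "nutrient_cycling": 0.01,
        "biodiversity": 0.12, "aesthetic_landscape": 0.05,
    },
}

#: Yuan per km² per year for one equivalent (1/7 of the study-region average
#: food price per unit area; a config scalar here).
DEFAULT_UNIT_EQUIVALENT_VALUE = 231427.0


def default_catalog(garden_plot_group: str = "forest land") -> ClassCatalog:
    """The 12-class legend with its vulnerability ranks and default valuation.

    Ranks run from 1 (building land, least vulnerable) to 12 (bare land, most
    vulnerable). The 12 classes collapse into the 8 valuation groups; the four
    forest classes map to "forest land" and the garden plot mapping is an
    assumption surfaced as the ``garden_plot_group`` argument (woody cover by
    default; pass ``"non-irrigated field"`` to treat it as cropland).
    """
    if garden_plot_group not in ESV_GROUPS:
        raise ValueError(f"garden_plot_group must be one of {ESV_GROUPS}")
    spec = [
        # code, name, F_i, esv group
        (1, "building land", 1, "building land"),
        (2, "arbor forest land", 2, "forest land"),
        (3, "bamboo forest land", 3, "forest land"),
        (4, "shrubland", 4, "forest land"),
        (5, "other forest land", 5, "forest land"),
        (6, "garden plot", 6, garden_plot_group),
        (7, "grassland", 7, "grassland"),
        (8, "non-irrigated field", 8, "non-irrigated field"),
        (9, "irrigated field", 9, "irrigated field"),
        (10, "wetland", 10, "wetland"),
        (11, "water", 11, "water"),
        (12, "bare land", 12, "bare land"),
    ]
    classes = tuple(LandUseClass(c, n, f, g) for c, n, f, g in spec)
    return ClassCatalog(
        classes=classes,
        unit_equivalent_value=DEFAULT_UNIT_EQUIVALENT_VALUE,
        equivalents={g: dict(v) for g, v in _DEFAULT_EQUIVALENTS.items()},
    )


def validate_catalog(catalog: ClassCatalog) -> list[str]:
    """Return a list of invariant violations (empty when the catalog is valid).

    Violations are returned, not raised, so callers can report all problems of
    a user-supplied catalog file at once.
    """
    violations: list[str] = []
    seen: dict[int, int] = {}
    for c in catalog.classes:
        seen[c.code] = seen.get(c.code, 0) + 1
    for code, n in seen.items():
        if n > 1:
            violations.append(f"duplicate class code {code} ({n} occurrences)")
    for c in catalog.classes:
        if c.code < 1:
            violations.append(f"class code {c.code} must be >= 1")
        if not 1 <= c.vulnerability_rank <= 12:
            violations.append(
                f"class code {c.code}: vulnerability_rank {c.vulnerability_rank} "
                "outside 1..12"
            )
        if c.esv_group not in catalog.equivalents:
            violations.append(
                f"class code {c.code}: esv_group {c.esv_group!r} has no "
                "equivalents row"
            )
    if not catalog.unit_equivalent_value > 0:
        violations.append(
            f"unit_equivalent_value must be > 0, got {catalog.unit_equivalent_value}"
        )
    for group, row in catalog.equivalents.items():
        for sub, val in row.items():
            if sub not in SERVICE_SUBCATEGORIES:
                violations.append(
                    f"equivalents[{group!r}]: unknown subcategory {sub!r}"
                )
            elif val < 0:
                violations.append(
                    f"equivalents[{group!r}][{sub!r}] = {val} is negative"
                )
    return violations


def coefficient_table(catalog: ClassCatalog) -> dict[int, dict[str, float]]:
    """Per-class service coefficients ``VC_i`` in 万元 (RMB 10⁴) per km².

    Returns ``{code: {subcategory: VC, ..., "total": sum}}`` where
    ``VC = equivalent_factor * unit_equivalent_value / 1e4``. Missing
    subcategories in a group's row count as zero.
    """
    problems = validate_catalog(catalog)
    if problems:
        raise ValueError("invalid catalog: " + "; ".join(problems))
    table: dict[int, dict[str, float]] = {}
    for c in catalog.classes:
        row = catalog.equivalents.get(c.esv_group)
        if row is None:
            raise KeyError(
                f"no equivalents row for esv group {c.esv_group!r} "
                f"(class code {c.code})"
            )
        vc = {
            s: row.get(s, 0.0) * catalog.unit_equivalent_value / 1e4
            for s in SERVICE_SUBCATEGORIES
        }
        vc["total"] = sum(vc[s] for s in SERVICE_SUBCATEGORIES)
        table[c.code] = vc
    return table


# ---------------------------------------------------------------------------
# Catalog file round-trip (YAML; strict unknown-key rejection)

_CLASS_KEYS = {"code", "name", "vulnerability_rank", "esv_group", "color"}
_TOP_KEYS = {"classes", "unit_equivalent_value", "equivalents"}


def save_catalog(catalog: ClassCatalog, path) -> None:
    doc = {
        "classes": [
            {k: v for k, v in {
                "code": c.code,
                "name": c.name,
                "vulnerability_rank": c.vulnerability_rank,
                "esv_group": c.esv_group,
                "color": c.color,
            }.items() if v is not None}
            for c in catalog.classes
        ],
        "unit_equivalent_value": catalog.unit_equivalent_value,
        "equivalents": {g: dict(row) for g, row in catalog.equivalents.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_catalog(path) -> ClassCatalog:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: catalog file must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown catalog keys {sorted(unknown)}")
    classes = []
    for entry in doc.get("classes", []):
        bad = set(entry) - _CLASS_KEYS
        if bad:
            raise ValueError(f"{path}: unknown class keys {sorted(bad)}")
        classes.append(LandUseClass(
            code=int(entry["code"]),
            name=str(entry["name"]),
            vulnerability_rank=int(entry["vulnerability_rank"]),
            esv_group=str(entry["esv_group"]),
            color=entry.get("color"),
        ))
    return ClassCatalog(
        classes=tuple(classes),
        unit_equivalent_value=float(doc["unit_equivalent_value"]),
        equivalents={
            str(g): {str(s): float(v) for s, v in row.items()}
            for g, row in doc.get("equivalents", {}).items()
        },
    )
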