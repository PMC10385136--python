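"""Core product-record types, nutrition-panel standardization, and table I/O.

A product record is one launched product (one barcode; distinct package sizes
of the same formulation carry distinct barcodes and count as distinct
products). Its back-of-pack nutrition information panel (NIP) is standardized
to a per-100 g or per-100 mL nutrient vector with energy in kJ, which is the
basis every downstream stage (nutrient-profiling score, eligibility criteria)
operates on.
"""

from __future__ import annotations

import json
import math
from decimal import ROUND_CEILING, ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

KCAL_TO_KJ = 4.184

#: nutrients that must be present on a usable NIP (per-100 basis after
#: standardization); fiber is deliberately not among them — a missing fiber
#: declaration is legal in Thailand and is handled by imputation
MANDATORY_NUTRIENTS = (
    "energy",
    "total_fat",
    "saturated_fat",
    "protein",
    "total_carbohydrate",
    "total_sugar",
    "sodium",
)

#: Thai RDA reference values (mg) used to convert %RDA declarations of
#: calcium and iron to mg; overridable via the ``rda`` argument
DEFAULT_RDA_MG = {"calcium": 800.0, "iron": 15.0}

INGREDIENT_DELIMITER = "; "


class PanelError(ValueError):
    """A record-level panel problem; ``reason`` routes the record to exclusion."""

    def __init__(self, message: str, reason: str | None = None):
        super().__init__(message)
        self.reason = reason


class SchemaError(ValueError):
    """A product table is missing mandatory columns."""

    def __init__(self, missing: Sequence[str]):
        super().__init__(f"missing mandatory columns: {', '.join(missing)}")
        self.missing = tuple(missing)


class NutrientPanel(BaseModel):
    """Standardized per-100 g/mL nutrient vector (energy in kJ)."""

    model_config = ConfigDict(frozen=True)

    basis: Literal["per100g", "per100mL"]
    serving_size: Optional[float] = Field(default=None, gt=0)
    energy: float = Field(ge=0)
    total_fat: float = Field(ge=0)
    saturated_fat: float = Field(ge=0)
    protein: float = Field(ge=0)
    total_carbohydrate: float = Field(ge=0)
    fiber: Optional[float] = Field(default=None, ge=0)
    total_sugar: float = Field(ge=0)
    sodium: float = Field(ge=0)
    calcium: Optional[float] = Field(default=None, ge=0)
    iron: Optional[float] = Field(default=None, ge=0)
    fvnl_nonconc_pct: Optional[float] = Field(default=None, ge=0, le=100)
    fvnl_conc_pct: Optional[float] = Field(default=None, ge=0, le=100)
    fiber_imputed: bool = False
    fvnl_imputed: bool = False
    less_than_adjusted: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _flag_inconsistencies(self) -> "NutrientPanel":
        # label data can be internally inconsistent; warn, never reject
        warns = list(self.warnings)
        if self.saturated_fat > self.total_fat + 1e-9 and "saturated_fat>total_fat" not in warns:
            warns.append("saturated_fat>total_fat")
        if self.total_sugar > self.total_carbohydrate + 1e-9 and "total_sugar>total_carbohydrate" not in warns:
            warns.append("total_sugar>total_carbohydrate")
        if tuple(warns) != self.warnings:
            object.__setattr__(self, "warnings", tuple(warns))
        return self


class ProductRecord(BaseModel):
    model_config = ConfigDict(frozen=False)

    barcode: str
    release_year: int
    manufacturer: str = ""
    product_name: str = ""
    description: str = ""
    package_descriptor: str = ""
    gnpd_major: str = ""
    gnpd_minor: str = ""
    ingredients: tuple[str, ...] = ()
    panel_per_serving: Optional[dict[str, Any]] = None
    panel_std: Optional[NutrientPanel] = None
    thcl_displayed: bool = False
    excluded: Optional[str] = None
    extras: dict[str, Any] = Field(default_factory=dict)


class RecordBatch(BaseModel):
    records: list[ProductRecord]
    provenance: str = ""

    @property
    def year_range(self) -> tuple[int, int] | None:
        if not self.records:
            return None
        years = [r.release_year for r in self.records]
        return (min(years), max(years))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flatten into one row per record with ``panel_*``-free flat columns."""
        rows = []
        for r in self.records:
            row: dict[str, Any] = {
                "barcode": r.barcode,
                "release_year": r.release_year,
                "manufacturer": r.manufacturer,
                "product_name": r.product_name,
                "description": r.description,
                "package_descriptor": r.package_descriptor,
                "gnpd_major": r.gnpd_major,
                "gnpd_minor": r.gnpd_minor,
                "ingredients": list(r.ingredients),
                "thcl_displayed": r.thcl_displayed,
                "excluded": r.excluded,
            }
            if r.panel_std is not None:
                p = r.panel_std
                row.update(
                    basis=p.basis,
                    serving_size=p.serving_size,
                    energy=p.energy,
                    total_fat=p.total_fat,
                    saturated_fat=p.saturated_fat,
                    protein=p.protein,
                    total_carbohydrate=p.total_carbohydrate,
                    fiber=p.fiber,
                    total_sugar=p.total_sugar,
                    sodium=p.sodium,
                    calcium=p.calcium,
                    iron=p.iron,
                    fvnl_nonconc_pct=p.fvnl_nonconc_pct,
                    fvnl_conc_pct=p.fvnl_conc_pct,
                    fiber_imputed=p.fiber_imputed,
                    fvnl_imputed=p.fvnl_imputed,
                )
            row.update(r.extras)
            rows.append(row)
        return pd.DataFrame(rows)


def apply_less_than_rule(
    declared: float | int | str, rule: Literal["nearest", "ceiling"] = "nearest"
) -> tuple[float, bool]:
    """Resolve a declared NIP value that may carry a "less than" qualifier.

    ``"<x"`` tokens map to the whole number closest to ``x`` (``nearest``,
    half-up: ``"<1.0"`` -> 1, ``"<0.5"`` -> 1, ``"<0.4"`` -> 0) or to
    ``ceil(x)`` under the ``ceiling`` variant. Plain numbers pass through.
    Returns ``(value, adjusted_flag)``.
    """
    if isinstance(declared, (int, float)):
        return float(declared), False
    token = declared.strip()
    if token.startswith("<"):
        body = token[1:].strip()
        try:
            bound = Decimal(body)
        except Exception as exc:
            raise ValueError(f"unparseable 'less than' token: {declared!r}") from exc
        mode = ROUND_HALF_UP if rule == "nearest" else ROUND_CEILING
        return float(bound.quantize(Decimal("1"), rounding=mode)), True
    try:
        return float(token), False
    except ValueError as exc:
        raise ValueError(f"unparseable declared value: {declared!r}") from exc


def standardize_panel(
    raw_values: Mapping[str, float | str | None],
    declared_basis: Literal["per_serving", "per100"],
    serving_size: float | None = None,
    energy_unit: Literal["kcal", "kJ"] = "kJ",
    basis: Literal["per100g", "per100mL"] = "per100g",
    rda: Mapping[str, float] | None = None,
    less_than_rule: Literal["nearest", "ceiling"] = "nearest",
) -> NutrientPanel:
    """Standardize a raw NIP to per-100 basis units with energy in kJ.

    ``raw_values`` maps nutrient names to numbers or declared strings
    (possibly "less than" tokens). Calcium and iron may be supplied as
    ``calcium_pct_rda`` / ``iron_pct_rda`` and are converted to mg using the
    Thai RDA reference values.

    Raises :class:`PanelError` (reason ``"no usable NIP"``) when a mandatory
    nutrient is absent or a per-serving panel lacks a serving size.
    """
    rda = dict(DEFAULT_RDA_MG, **(rda or {}))

    if declared_basis == "per_serving":
        if serving_size is None or not serving_size > 0:
            raise PanelError(
                "per-serving panel without a positive serving size", reason="no usable NIP"
            )
        scale = 100.0 / serving_size
    else:
        scale = 1.0

    values: dict[str, float] = {}
    adjusted: list[str] = []
    for key, raw in raw_values.items():
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            continue
        value, flag = apply_less_than_rule(raw, rule=less_than_rule)
        if value < 0:
            raise PanelError(f"negative declared value for {key}: {value}")
        if flag:
            adjusted.append(key)
        values[key] = value

    missing = [k for k in MANDATORY_NUTRIENTS if k not in values]
    if missing:
        raise PanelError(
            f"mandatory nutrients absent: {', '.join(missing)}", reason="no usable NIP"
        )

    for mineral in ("calcium", "iron"):
        pct_key = f"{mineral}_pct_rda"
        if pct_key in values and mineral not in values:
            values[mineral] = values.pop(pct_key) / 100.0 * rda[mineral]
        values.pop(pct_key, None)

    out: dict[str, float] = {}
    for key, value in values.items():
        out[key] = value * scale
    if energy_unit == "kcal":
        out["energy"] = out["energy"] * KCAL_TO_KJ

    return NutrientPanel(
        basis=basis,
        serving_size=serving_size,
        energy=out["energy"],
        total_fat=out["total_fat"],
        saturated_fat=out["saturated_fat"],
        protein=out["protein"],
        total_carbohydrate=out["total_carbohydrate"],
        fiber=out.get("fiber"),
        total_sugar=out["total_sugar"],
        sodium=out["sodium"],
        calcium=out.get("calcium"),
        iron=out.get("iron"),
        fvnl_nonconc_pct=out.get("fvnl_nonconc_pct"),
        fvnl_conc_pct=out.get("fvnl_conc_pct"),
        less_than_adjusted=tuple(adjusted),
    )


def dedup_records(batch: RecordBatch) -> tuple[RecordBatch, int]:
    """Drop repeated barcodes, keeping the first-seen record per barcode."""
    seen: set[str] = set()
    kept: list[ProductRecord] = []
    for record in batch.records:
        if record.barcode in seen:
            continue
        seen.add(record.barcode)
        kept.append(record)
    removed = len(batch.records) - len(kept)
    return RecordBatch(records=kept, provenance=batch.provenance), removed


# ---------------------------------------------------------------------------
# product-table I/O

#: canonical column name -> file column name, per dialect
DIALECTS: dict[str, dict[str, str]] = {
    "fopnl": {},
    "mintel-like": {
        "barcode": "Barcode",
        "release_year": "Year of Launch",
        "manufacturer": "Ultimate Company",
        "product_name": "Product Name",
        "description": "Product Description",
        "package_descriptor": "Package Size",
        "gnpd_major": "Category",
        "gnpd_minor": "Sub-Category",
        "ingredients": "Ingredient List",
        "thcl_displayed": "Healthier Choice Logo",
    },
}

_MANDATORY_COLUMNS = ("barcode", "release_year", "gnpd_major", "gnpd_minor")
_PANEL_COLUMNS = (
    "basis",
    "serving_size",
    "energy",
    "total_fat",
    "saturated_fat",
    "protein",
    "total_carbohydrate",
    "fiber",
    "total_sugar",
    "sodium",
    "calcium",
    "iron",
    "fvnl_nonconc_pct",
    "fvnl_conc_pct",
)
_KNOWN_COLUMNS = set(_MANDATORY_COLUMNS) | set(_PANEL_COLUMNS) | {
    "manufacturer",
    "product_name",
    "description",
    "package_descriptor",
    "ingredients",
    "thcl_displayed",
    "excluded",
    "fiber_imputed",
    "fvnl_imputed",
}


def _resolve_dialect(dialect: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError as exc:
            raise ValueError(f"unknown dialect {dialect!r}") from exc
    return dict(dialect)


def _row_to_record(row: Mapping[str, Any]) -> ProductRecord:
    def _get(key: str, default: Any = "") -> Any:
        v = row.get(key, default)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return default
        return v

    ingredients = _get("ingredients", ())
    if isinstance(ingredients, str):
        ingredients = tuple(s.strip() for s in ingredients.split(INGREDIENT_DELIMITER.strip()) if s.strip())
    else:
        ingredients = tuple(ingredients)

    panel = None
    if "energy" in row and not pd.isna(row.get("energy")):
        fields: dict[str, Any] = {}
        for col in _PANEL_COLUMNS:
            v = row.get(col)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                fields[col] = v
        fields.setdefault("basis", "per100g")
        fields["fiber_imputed"] = bool(_get("fiber_imputed", False))
        fields["fvnl_imputed"] = bool(_get("fvnl_imputed", False))
        panel = NutrientPanel(**fields)

    extras = {k: v for k, v in row.items() if k not in _KNOWN_COLUMNS}
    displayed = _get("thcl_displayed", False)
    if isinstance(displayed, str):
        displayed = displayed.strip().lower() in {"1", "true", "yes", "y"}
    return ProductRecord(
        barcode=str(_get("barcode")),
        release_year=int(row["release_year"]),
        manufacturer=str(_get("manufacturer")),
        product_name=str(_get("product_name")),
        description=str(_get("description")),
        package_descriptor=str(_get("package_descriptor")),
        gnpd_major=str(_get("gnpd_major")),
        gnpd_minor=str(_get("gnpd_minor")),
        ingredients=ingredients,
        panel_std=panel,
        thcl_displayed=bool(displayed),
        excluded=_get("excluded", None) or None,
        extras=extras,
    )


def read_records(
    path: str | Path, dialect: str | Mapping[str, str] = "fopnl"
) -> RecordBatch:
    """Read a product table (CSV or JSON-lines, inferred from the extension)."""
    path = Path(path)
    mapping = _resolve_dialect(dialect)
    reverse = {v: k for k, v in mapping.items()}

    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        rows = [json.loads(line) for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path)
    frame = frame.rename(columns=reverse)

    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(missing)
    if frame["barcode"].isna().any():
        raise SchemaError(["barcode (empty values)"])

    records = [_row_to_record(row) for row in frame.to_dict(orient="records")]
    return RecordBatch(records=records, provenance=str(path))


def write_records(batch: RecordBatch, path: str | Path) -> None:
    """Write a product table as CSV or JSON-lines (by extension); round-trips
    with :func:`read_records` under the default dialect."""
    path = Path(path)
    frame = batch.to_frame()
    if "ingredients" in frame.columns:
        frame = frame.assign(
            ingredients=frame["ingredients"].map(lambda xs: INGREDIENT_DELIMITER.join(xs))
        )
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with open(path, "w", encoding="utf-8") as fh:
            for row in frame.to_dict(orient="records"):
                clean = {k: v for k, v in row.items() if not (isinstance(v, float) and math.isnan(v))}
                fh.write(json.dumps(clean) + "\n")
    else:
        frame.to_csv(path, index=False)
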