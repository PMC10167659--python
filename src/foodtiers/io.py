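"""Tabular input/output and the linkage / exclusion stage.

Catalog and sales tables are UTF-8 delimited text (comma by default,
tab accepted) with one header row and fixed column names. Missing
optional fields are empty cells and parse to ``None``, never to zero.

:func:`link_and_filter` joins sales to the product catalog on the
product code and removes products that lack the information every
downstream classifier needs, partitioning the removals into auditable
reasons with fixed precedence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ValidationError

from .records import CoreStatus, ProductRecord, SalesRecord

__all__ = [
    "CATALOG_COLUMNS",
    "SALES_COLUMNS",
    "EXCLUSION_REASONS",
    "CatalogError",
    "ExclusionConfig",
    "ExclusionReport",
    "LinkedDataset",
    "read_catalog",
    "write_catalog",
    "read_sales",
    "write_sales",
    "link_and_filter",
]

CATALOG_COLUMNS: tuple[str, ...] = (
    "product_id",
    "description",
    "net_weight",
    "serving_size",
    "package_size",
    "energy",
    "saturated_fat",
    "total_sugars",
    "added_sugars",
    "sodium",
    "fibre",
    "pct_fruit_veg_juice",
    "artificially_sweetened",
    "contains_confectionery",
    "deep_fried",
    "hsr",
    "core_source_db",
    "core_abs",
    "ahs_minor_group",
    "source_db_category",
    "hsr_exempt",
    "ntscg_exempt",
)

SALES_COLUMNS: tuple[str, ...] = ("product_id", "store_id", "quantity_sold")

#: Exclusion reasons in precedence order: a product missing several
#: requirements is counted once, under the first matching reason.
EXCLUSION_REASONS: tuple[str, ...] = (
    "not_in_composition_db",
    "missing_added_sugar",
    "missing_ingredients",
    "missing_nutrition_panel",
    "system_exempt",
)

_FLOAT_FIELDS = {
    "net_weight",
    "serving_size",
    "package_size",
    "energy",
    "saturated_fat",
    "total_sugars",
    "added_sugars",
    "sodium",
    "fibre",
    "pct_fruit_veg_juice",
    "hsr",
}
_BOOL_FIELDS = {
    "artificially_sweetened",
    "contains_confectionery",
    "deep_fried",
    "hsr_exempt",
    "ntscg_exempt",
}


class CatalogError(ValueError):
    """Raised for malformed catalog or sales tables."""


def _sep_for(path: Path, dialect: Optional[str]) -> str:
    if dialect in ("tsv", "tab", "\t"):
        return "\t"
    if dialect in (None, "csv", ","):
        return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raise CatalogError(f"unknown table dialect {dialect!r}")


def _parse_cell(field: str, raw: str) -> object:
    if raw == "" or raw is None:
        return None
    if field in _FLOAT_FIELDS:
        return float(raw)
    if field in _BOOL_FIELDS:
        low = raw.strip().lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return raw


def read_catalog(path: str | Path, dialect: Optional[str] = None) -> list[ProductRecord]:
    """Read a product catalog table into validated :class:`ProductRecord` s.

    Raises :class:`CatalogError` naming the offending row and field on
    malformed input, and on duplicate product identifiers.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(frame.columns)
    if missing:
        raise CatalogError(f"catalog {path} is missing columns: {sorted(missing)}")

    products: list[ProductRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # header is line 1
        values: dict[str, object] = {}
        record = dict(zip(frame.columns, row))
        for field in CATALOG_COLUMNS:
            try:
                values[field] = _parse_cell(field, record[field])
            except ValueError as exc:
                raise CatalogError(f"{path} line {idx}, field {field!r}: {exc}") from exc
        for field in ("hsr_exempt", "ntscg_exempt"):
            if values[field] is None:
                values[field] = False
        for field in ("description", "ahs_minor_group", "source_db_category"):
            if values[field] is None:
                values[field] = ""
        try:
            product = ProductRecord(**values)
        except ValidationError as exc:
            raise CatalogError(f"{path} line {idx}: {exc}") from exc
        if product.product_id in seen:
            raise CatalogError(f"{path} line {idx}: duplicate product_id {product.product_id!r}")
        seen.add(product.product_id)
        products.append(product)
    return products


def catalog_to_frame(products: Iterable[ProductRecord]) -> pd.DataFrame:
    rows = []
    for p in products:
        d = p.model_dump()
        for key in ("core_source_db", "core_abs"):
            if isinstance(d[key], CoreStatus):
                d[key] = d[key].value
        rows.append(d)
    return pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))


def write_catalog(products: Iterable[ProductRecord], path: str | Path, dialect: Optional[str] = None) -> None:
    """Write a catalog table; round-trips every field through :func:`read_catalog`."""
    path = Path(path)
    frame = catalog_to_frame(products)
    for field in _BOOL_FIELDS:
        frame[field] = frame[field].map(
            lambda v: "" if v is None else ("true" if v else "false")
        )
    frame.to_csv(path, sep=_sep_for(path, dialect), index=False, float_format="%.17g")


def read_sales(path: str | Path, dialect: Optional[str] = None) -> list[SalesRecord]:
    """Read a sales table. Quantities must be non-negative and integral."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    missing = set(SALES_COLUMNS) - set(frame.columns)
    if missing:
        raise CatalogError(f"sales {path} is missing columns: {sorted(missing)}")
    records: list[SalesRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(frame.columns, row))
        raw_q = rec["quantity_sold"]
        try:
            q = float(raw_q)
        except ValueError as exc:
            raise CatalogError(f"{path} line {idx}, field 'quantity_sold': {raw_q!r}") from exc
        if q != int(q):
            raise CatalogError(f"{path} line {idx}: quantity_sold {raw_q!r} is not integral")
        if q < 0:
            raise CatalogError(f"{path} line {idx}: quantity_sold {raw_q!r} is negative")
        key = (rec["product_id"], rec["store_id"])
        if key in seen:
            raise CatalogError(f"{path} line {idx}: duplicate (product_id, store_id) {key}")
        seen.add(key)
        records.append(
            SalesRecord(product_id=rec["product_id"], store_id=rec["store_id"], quantity_sold=int(q))
        )
    return records


def sales_to_frame(sales: Iterable[SalesRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [s.model_dump() for s in sales], columns=list(SALES_COLUMNS)
    ).astype({"quantity_sold": "int64"})


def write_sales(sales: Iterable[SalesRecord], path: str | Path, dialect: Optional[str] = None) -> None:
    path = Path(path)
    sales_to_frame(sales).to_csv(path, sep=_sep_for(path, dialect), index=False)


class ExclusionConfig(BaseModel):
    """Which exclusion reasons are enforced by :func:`link_and_filter`.

    Each flag enables one reason; precedence between reasons is fixed
    by :data:`EXCLUSION_REASONS`.
    """

    exclude_not_in_composition_db: bool = True
    exclude_missing_added_sugar: bool = True
    exclude_missing_ingredients: bool = True
    exclude_missing_nutrition_panel: bool = True
    exclude_exempt: bool = True


@dataclasses.dataclass
class ExclusionReport:
    """Accounting of the linkage stage: every input product is either
    retained or excluded under exactly one reason."""

    n_input: int
    n_excluded_by_reason: dict[str, int]
    n_retained: int
    excluded_share_of_quantity: float
    excluded_ids_by_reason: dict[str, list[str]] = dataclasses.field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_reason.values())


@dataclasses.dataclass
class LinkedDataset:
    """Analysis-ready dataset: retained products plus their sales.

    ``quantity`` is the default analysis view — total quantity per
    product summed over stores. ``sales`` keeps the per-store rows for
    the store-level sensitivity analysis.
    """

    products: list[ProductRecord]
    sales: pd.DataFrame  # columns product_id, store_id, quantity_sold
    quantity: pd.Series  # index product_id -> int total units

    @property
    def product_by_id(self) -> dict[str, ProductRecord]:
        return {p.product_id: p for p in self.products}

    def with_products(self, products: Sequence[ProductRecord]) -> "LinkedDataset":
        keep = {p.product_id for p in products}
        sales = self.sales[self.sales["product_id"].isin(keep)].reset_index(drop=True)
        quantity = self.quantity.reindex([p.product_id for p in products]).fillna(0).astype("int64")
        return LinkedDataset(products=list(products), sales=sales, quantity=quantity)


# Panel fields a product must carry to be classifiable by every system
# (net weight and energy feed the outcome formulas; saturated fat,
# sugars and sodium feed NTSCG nutrient cut-offs; serving size feeds
# per-serve cut-offs).
_PANEL_FIELDS = ("net_weight", "energy", "saturated_fat", "total_sugars", "sodium", "serving_size")
_INGREDIENT_FLAGS = ("artificially_sweetened", "contains_confectionery", "deep_fried")


def _exclusion_reason(product: ProductRecord, config: ExclusionConfig) -> Optional[str]:
    if config.exclude_missing_added_sugar and product.added_sugars is None:
        return "missing_added_sugar"
    if config.exclude_missing_ingredients and any(
        getattr(product, f) is None for f in _INGREDIENT_FLAGS
    ):
        return "missing_ingredients"
    if config.exclude_missing_nutrition_panel and any(
        getattr(product, f) is None for f in _PANEL_FIELDS
    ):
        return "missing_nutrition_panel"
    if config.exclude_exempt and (
        product.hsr_exempt
        or product.ntscg_exempt
        or product.hsr is None
        or product.core_source_db is None
    ):
        # Exempt categories (plain sugar, infant formula, supplementary
        # foods) sit outside the HSR and NTSCG; a product with no HSR or
        # no core flag is likewise unratable by the systems.
        return "system_exempt"
    return None


def link_and_filter(
    catalog: Sequence[ProductRecord],
    sales: Sequence[SalesRecord] | pd.DataFrame,
    config: Optional[ExclusionConfig] = None,
) -> tuple[LinkedDataset, ExclusionReport]:
    """Link sales to the catalog and drop products unusable downstream.

    The input product set is the union of catalog products and product
    codes appearing in the sales table; sales codes absent from the
    catalog are excluded under ``not_in_composition_db``. All problems
    become exclusion reasons — this stage never raises on content.
    """
    config = config or ExclusionConfig()
    sales_frame = sales if isinstance(sales, pd.DataFrame) else sales_to_frame(sales)
    catalog_ids = {p.product_id for p in catalog}
    sales_ids = set(sales_frame["product_id"]) if len(sales_frame) else set()

    excluded: dict[str, list[str]] = {r: [] for r in EXCLUSION_REASONS}
    if config.exclude_not_in_composition_db:
        excluded["not_in_composition_db"] = sorted(sales_ids - catalog_ids)

    retained: list[ProductRecord] = []
    for product in catalog:
        reason = _exclusion_reason(product, config)
        if reason is None:
            retained.append(product)
        else:
            excluded[reason].append(product.product_id)

    excluded_ids = {pid for ids in excluded.values() for pid in ids}
    retained_ids = [p.product_id for p in retained]

    total_q = int(sales_frame["quantity_sold"].sum()) if len(sales_frame) else 0
    if total_q > 0:
        excl_q = int(
            sales_frame.loc[sales_frame["product_id"].isin(excluded_ids), "quantity_sold"].sum()
        )
        excluded_share = 100.0 * excl_q / total_q
    else:
        excluded_share = 0.0

    kept_sales = sales_frame[sales_frame["product_id"].isin(retained_ids)].reset_index(drop=True)
    quantity = (
        kept_sales.groupby("product_id")["quantity_sold"].sum()
        if len(kept_sales)
        else pd.Series(dtype="int64")
    )
    quantity = quantity.reindex(retained_ids).fillna(0).astype("int64")
    quantity.index.name = "product_id"

    n_input = len(catalog) + len(excluded["not_in_composition_db"])
    report = ExclusionReport(
        n_input=n_input,
        n_excluded_by_reason={r: len(ids) for r, ids in excluded.items()},
        n_retained=len(retained),
        excluded_share_of_quantity=excluded_share,
        excluded_ids_by_reason={r: ids for r, ids in excluded.items()},
    )
    dataset = LinkedDataset(products=retained, sales=kept_sales, quantity=quantity)
    return dataset, report
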