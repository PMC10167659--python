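"""Domain records for packaged products and store sales.

A :class:`ProductRecord` is one unique packaged food or non-alcoholic
beverage product (identified by its barcode / Universal Product Code),
carrying the per-100 g nutrition panel, serving and package sizes, the
Health Star Rating (HSR) assigned by the composition database, two
core/discretionary classifications (one from the source composition
database, one following the Australian Bureau of Statistics / Australian
Health Survey principles), ingredient-derived flags, and category codes.

A :class:`SalesRecord` is the total quantity of one product sold in one
store over the study window.

Missing values are represented as ``None`` (explicit absence), never as
zero; downstream classifiers declare their behaviour on absence.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "CoreStatus",
    "ProductRecord",
    "SalesRecord",
    "HALF_STAR_GRID",
    "is_half_star",
]

#: Valid Health Star Rating values: 0.5 to 5.0 stars in half-star steps.
HALF_STAR_GRID: tuple[float, ...] = tuple(0.5 * k for k in range(1, 11))


def is_half_star(value: float) -> bool:
    """True if *value* lies on the 0.5–5.0 half-star grid."""
    return any(abs(value - g) < 1e-9 for g in HALF_STAR_GRID)


class CoreStatus(str, enum.Enum):
    """Australian Dietary Guidelines dichotomy.

    Core foods supply essential nutrients for growth and development;
    discretionary foods are energy-dense, high in saturated fat, sugars
    or sodium, and not required in a healthy diet.
    """

    CORE = "core"
    DISCRETIONARY = "discretionary"


class ProductRecord(BaseModel):
    """One unique packaged product with composition and classification inputs.

    All nutrient fields are per 100 g of product. Beverage volumes in
    millilitres are treated as grams (density 1); no density data exist
    for the product range and package weight/volume is used
    interchangeably in practice.
    """

    model_config = ConfigDict(validate_assignment=True)

    product_id: str
    description: str = ""
    net_weight: Optional[float] = Field(default=None, ge=0, description="g per unit sold")
    serving_size: Optional[float] = Field(default=None, ge=0, description="g per manufacturer serve")
    package_size: Optional[float] = Field(default=None, ge=0, description="g per package")
    energy: Optional[float] = Field(default=None, ge=0, description="kJ per 100 g")
    saturated_fat: Optional[float] = Field(default=None, ge=0, description="g per 100 g")
    total_sugars: Optional[float] = Field(default=None, ge=0, description="g per 100 g")
    added_sugars: Optional[float] = Field(default=None, ge=0, description="estimated g per 100 g")
    sodium: Optional[float] = Field(default=None, ge=0, description="mg per 100 g")
    fibre: Optional[float] = Field(default=None, ge=0, description="g per 100 g")
    pct_fruit_veg_juice: Optional[float] = Field(default=None, ge=0, le=100)
    artificially_sweetened: Optional[bool] = None
    contains_confectionery: Optional[bool] = None
    deep_fried: Optional[bool] = None
    hsr: Optional[float] = None
    core_source_db: Optional[CoreStatus] = None
    core_abs: Optional[CoreStatus] = None
    ahs_minor_group: str = ""
    source_db_category: str = ""
    hsr_exempt: bool = False
    ntscg_exempt: bool = False

    @field_validator("hsr")
    @classmethod
    def _hsr_on_grid(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not is_half_star(v):
            raise ValueError(f"hsr must lie on the half-star grid 0.5-5.0, got {v}")
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "ProductRecord":
        if (
            self.added_sugars is not None
            and self.total_sugars is not None
            and self.added_sugars > self.total_sugars + 1e-9
        ):
            raise ValueError(
                f"added_sugars ({self.added_sugars}) exceeds total_sugars "
                f"({self.total_sugars})"
            )
        if (
            self.serving_size is not None
            and self.package_size is not None
            and self.serving_size > self.package_size + 1e-9
        ):
            raise ValueError(
                f"serving_size ({self.serving_size}) exceeds package_size "
                f"({self.package_size})"
            )
        return self

    def core_status(self, core_source: str = "source_db") -> Optional[CoreStatus]:
        """Governing core/discretionary flag under the chosen source.

        ``core_source`` is ``"source_db"`` (composition-database flag, the
        app's default) or ``"abs"`` (AHS/ABS flag).
        """
        if core_source == "source_db":
            return self.core_source_db
        if core_source == "abs":
            return self.core_abs
        raise ValueError(f"unknown core_source {core_source!r}")


class SalesRecord(BaseModel):
    """Quantity of one product sold at one store over the study window."""

    product_id: str
    store_id: str
    quantity_sold: int = Field(ge=0)
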