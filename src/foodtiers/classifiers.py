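"""The three healthiness classifiers and the common three-tier scale.

* **Thumbs** — four-level rating (double thumbs up, thumbs up, thumbs
  sideways, thumbs down) derived from a product's Health Star Rating
  (HSR) band and its core/discretionary status. The defining structural
  property is that no discretionary product can ever receive thumbs up
  or double thumbs up.
* **HSR tiers** — the 0.5–5.0 half-star front-of-pack score collapsed
  to three tiers; 3.5 stars and above is the healthy tier.
* **NTSCG** — Northern Territory School Canteen Guidelines traffic
  lights (Green/Amber/Red), implemented as a declarative, first-match
  rule engine over food-category matchers with conditional nutrient,
  ingredient-flag, juice-content and serving-size overrides.

All three map onto a common :class:`Tier` scale (healthy > somewhat
healthy > unhealthy) for cross-system comparison.
"""

from __future__ import annotations

import dataclasses
import enum
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .records import HALF_STAR_GRID, CoreStatus, ProductRecord, is_half_star

__all__ = [
    "Tier",
    "ThumbsRating",
    "NTSCGRating",
    "ServingBasis",
    "HSRTierBoundaries",
    "ThumbsRuleTable",
    "NTSCGCondition",
    "NTSCGRule",
    "NTSCGRuleSet",
    "NTSCGResult",
    "MissingFieldError",
    "classify_hsr_tier",
    "classify_thumbs",
    "classify_ntscg",
    "map_to_tier",
    "default_ntscg_ruleset",
]


class Tier(enum.IntEnum):
    """Common healthiness scale; larger is healthier."""

    UNHEALTHY = 0
    SOMEWHAT_HEALTHY = 1
    HEALTHY = 2


class ThumbsRating(enum.IntEnum):
    DOWN = 0
    SIDEWAYS = 1
    UP = 2
    DOUBLE_UP = 3


class NTSCGRating(enum.IntEnum):
    RED = 0
    AMBER = 1
    GREEN = 2


ServingBasis = Literal["manufacturer_serve", "package_size"]

_THUMBS_TO_TIER = {
    ThumbsRating.DOUBLE_UP: Tier.HEALTHY,
    ThumbsRating.UP: Tier.HEALTHY,
    ThumbsRating.SIDEWAYS: Tier.SOMEWHAT_HEALTHY,
    ThumbsRating.DOWN: Tier.UNHEALTHY,
}
_NTSCG_TO_TIER = {
    NTSCGRating.GREEN: Tier.HEALTHY,
    NTSCGRating.AMBER: Tier.SOMEWHAT_HEALTHY,
    NTSCGRating.RED: Tier.UNHEALTHY,
}


def map_to_tier(rating: Union[Tier, ThumbsRating, NTSCGRating]) -> Tier:
    """Collapse any system's rating onto the common three-tier scale."""
    if isinstance(rating, Tier):
        return rating
    if isinstance(rating, ThumbsRating):
        return _THUMBS_TO_TIER[rating]
    if isinstance(rating, NTSCGRating):
        return _NTSCG_TO_TIER[rating]
    raise TypeError(f"cannot map {rating!r} to a tier")


class MissingFieldError(ValueError):
    """A classifier needed a product field that is absent."""


class HSRTierBoundaries(BaseModel):
    """Cut points collapsing the half-star HSR to three tiers.

    ``hsr >= healthy_min`` is healthy, ``hsr <= unhealthy_max`` is
    unhealthy, the open interval between is somewhat healthy. The
    healthy cut of 3.5 stars follows the canteen-strategy alignment
    convention; the 2.0 unhealthy cut is a configurable assumption.
    """

    healthy_min: float = 3.5
    unhealthy_max: float = 2.0

    @model_validator(mode="after")
    def _ordered_on_grid(self) -> "HSRTierBoundaries":
        for name in ("healthy_min", "unhealthy_max"):
            if not is_half_star(getattr(self, name)):
                raise ValueError(f"{name} must be on the half-star grid")
        if not self.unhealthy_max < self.healthy_min - 0.25:
            raise ValueError("the somewhat-healthy interval must be non-empty")
        return self


def classify_hsr_tier(
    hsr: Optional[float], boundaries: Optional[HSRTierBoundaries] = None
) -> Tier:
    """Tier of a Health Star Rating under the given boundaries."""
    if hsr is None:
        raise MissingFieldError(
            "product has no HSR; exclude it or mark it system-exempt upstream"
        )
    if not is_half_star(hsr):
        raise ValueError(f"hsr {hsr} is not on the half-star grid")
    boundaries = boundaries or HSRTierBoundaries()
    if hsr >= boundaries.healthy_min:
        return Tier.HEALTHY
    if hsr <= boundaries.unhealthy_max:
        return Tier.UNHEALTHY
    return Tier.SOMEWHAT_HEALTHY


class ThumbsRuleTable(BaseModel):
    """Banded lookup (core status × HSR) → Thumbs rating.

    Default bands: core products earn double thumbs up from 4.5 stars,
    thumbs up from 3.5, thumbs sideways above 2.0 and thumbs down at
    2.0 or below; discretionary products are capped at thumbs sideways
    (from 3.5 stars) and get thumbs down otherwise. The cap is a hard
    invariant — no band configuration may award a discretionary product
    thumbs up or double thumbs up.
    """

    double_up_min: float = 4.5
    up_min: float = 3.5
    core_down_max: float = 2.0
    discretionary_sideways_min: float = 3.5

    @model_validator(mode="after")
    def _valid_bands(self) -> "ThumbsRuleTable":
        for name in ("double_up_min", "up_min", "core_down_max", "discretionary_sideways_min"):
            if not is_half_star(getattr(self, name)):
                raise ValueError(f"{name} must be on the half-star grid")
        if not self.core_down_max < self.up_min <= self.double_up_min:
            raise ValueError("bands must satisfy core_down_max < up_min <= double_up_min")
        return self

    def rating_for(self, core_status: CoreStatus, hsr: float) -> ThumbsRating:
        """Total over the full (core status × half-star) grid."""
        if not is_half_star(hsr):
            raise ValueError(f"hsr {hsr} is not on the half-star grid")
        if core_status is CoreStatus.CORE:
            if hsr >= self.double_up_min:
                return ThumbsRating.DOUBLE_UP
            if hsr >= self.up_min:
                return ThumbsRating.UP
            if hsr > self.core_down_max:
                return ThumbsRating.SIDEWAYS
            return ThumbsRating.DOWN
        if hsr >= self.discretionary_sideways_min:
            return ThumbsRating.SIDEWAYS
        return ThumbsRating.DOWN

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThumbsRuleTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


def classify_thumbs(
    product: ProductRecord,
    table: Optional[ThumbsRuleTable] = None,
    core_source: str = "source_db",
) -> ThumbsRating:
    """Thumbs rating of a product from its HSR and governing core flag."""
    table = table or ThumbsRuleTable()
    if product.hsr is None:
        raise MissingFieldError(f"product {product.product_id}: hsr is absent")
    status = product.core_status(core_source)
    if status is None:
        raise MissingFieldError(
            f"product {product.product_id}: core flag ({core_source}) is absent"
        )
    return table.rating_for(status, product.hsr)


# --- NTSCG rule engine -------------------------------------------------

_NUTRIENT_FIELDS = ("energy", "saturated_fat", "total_sugars", "added_sugars", "sodium", "fibre")
_FLAG_FIELDS = ("artificially_sweetened", "contains_confectionery", "deep_fried")
_OPS = {
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "eq": lambda a, b: a == b,
}


class NTSCGCondition(BaseModel):
    """One predicate of an NTSCG rule.

    ``field`` is a nutrient (evaluated per 100 g or per serve), an
    ingredient flag, ``pct_fruit_veg_juice`` or ``serving_size`` (the
    serve amount in grams under the chosen basis). ``source`` records
    whether the threshold is quoted guidance or a placeholder to be
    replaced from the authoritative guideline tables.
    """

    field: str
    op: Literal["gt", "ge", "lt", "le", "eq"]
    threshold: Union[bool, float]
    basis: Literal["per_100g", "per_serve"] = "per_100g"
    source: Literal["guideline", "assumed"] = "assumed"

    @model_validator(mode="after")
    def _sane(self) -> "NTSCGCondition":
        known = set(_NUTRIENT_FIELDS) | set(_FLAG_FIELDS) | {"pct_fruit_veg_juice", "serving_size"}
        if self.field not in known:
            raise ValueError(f"condition references unknown field {self.field!r}")
        if self.field in _FLAG_FIELDS:
            if self.op != "eq" or not isinstance(self.threshold, bool):
                raise ValueError(f"flag condition on {self.field!r} must be eq true/false")
        elif isinstance(self.threshold, bool):
            raise ValueError(f"numeric condition on {self.field!r} has boolean threshold")
        elif self.threshold < 0:
            raise ValueError("thresholds must be non-negative")
        return self

    def _serve_amount(self, product: ProductRecord, basis: ServingBasis) -> float:
        attr = "serving_size" if basis == "manufacturer_serve" else "package_size"
        amount = getattr(product, attr)
        if amount is None:
            raise MissingFieldError(
                f"product {product.product_id}: {attr} required for a per-serve "
                f"condition under the {basis} basis"
            )
        return amount

    def value_of(self, product: ProductRecord, basis: ServingBasis) -> Union[bool, float]:
        if self.field in _FLAG_FIELDS:
            flag = getattr(product, self.field)
            if flag is None:
                raise MissingFieldError(
                    f"product {product.product_id}: ingredient flag {self.field} absent"
                )
            return flag
        if self.field == "serving_size":
            return self._serve_amount(product, basis)
        raw = getattr(product, self.field)
        if raw is None:
            raise MissingFieldError(
                f"product {product.product_id}: field {self.field} absent"
            )
        if self.basis == "per_serve":
            return raw * self._serve_amount(product, basis) / 100.0
        return raw

    def is_met(self, product: ProductRecord, basis: ServingBasis) -> bool:
        return _OPS[self.op](self.value_of(product, basis), self.threshold)

    def describe(self) -> str:
        basis = f" {self.basis}" if self.field in _NUTRIENT_FIELDS else ""
        return f"{self.field}{basis} {self.op} {self.threshold}"


class NTSCGRule(BaseModel):
    """Category rule: base traffic light plus conditional overrides.

    The first rule whose ``match`` set contains the product's AHS minor
    group applies; if any condition is met the rule's ``if_met`` rating
    replaces the base rating.
    """

    id: str
    match: list[str] = Field(min_length=1)
    base: NTSCGRating
    conditions: list[NTSCGCondition] = Field(default_factory=list)
    if_met: Optional[NTSCGRating] = None

    @model_validator(mode="after")
    def _override_present(self) -> "NTSCGRule":
        if self.conditions and self.if_met is None:
            raise ValueError(f"rule {self.id!r} has conditions but no if_met rating")
        return self

    @field_validator("base", "if_met", mode="before")
    @classmethod
    def _parse_rating(cls, v: object) -> object:
        if isinstance(v, str):
            return NTSCGRating[v.upper()]
        return v


@dataclasses.dataclass
class NTSCGResult:
    """Rating plus the explain record that justifies it."""

    rating: NTSCGRating
    rule_id: Optional[str]  # None when the fallback default applied
    conditions_evaluated: list[tuple[str, bool]]

    @property
    def tier(self) -> Tier:
        return map_to_tier(self.rating)


class NTSCGRuleSet(BaseModel):
    """Ordered traffic-light rules with a fallback for unmatched products."""

    schema_version: int = 1
    default_rating: NTSCGRating = NTSCGRating.AMBER
    rules: list[NTSCGRule] = Field(default_factory=list)

    @field_validator("default_rating", mode="before")
    @classmethod
    def _parse_rating(cls, v: object) -> object:
        if isinstance(v, str):
            return NTSCGRating[v.upper()]
        return v

    def matched_categories(self) -> set[str]:
        return {c for rule in self.rules for c in rule.match}

    def rule_for(self, ahs_minor_group: str) -> Optional[NTSCGRule]:
        for rule in self.rules:
            if ahs_minor_group in rule.match:
                return rule
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NTSCGRuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        data["default_rating"] = NTSCGRating(self.default_rating).name
        for rule, dumped in zip(self.rules, data["rules"]):
            dumped["base"] = NTSCGRating(rule.base).name
            if rule.if_met is not None:
                dumped["if_met"] = NTSCGRating(rule.if_met).name
            else:
                dumped.pop("if_met", None)
            if not rule.conditions:
                dumped.pop("conditions", None)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def default_ntscg_ruleset() -> NTSCGRuleSet:
    """The ruleset shipped with the package (``data/ntscg_rules.yaml``).

    Thresholds marked ``source: assumed`` in the file are placeholders
    standing in for the authoritative guideline tables and are meant to
    be edited; the rule engine, not the numbers, is the contract.
    """
    ref = resources.files("foodtiers").joinpath("data/ntscg_rules.yaml")
    with resources.as_file(ref) as path:
        return NTSCGRuleSet.from_yaml(path)


def classify_ntscg(
    product: ProductRecord,
    ruleset: Optional[NTSCGRuleSet] = None,
    serving_basis: ServingBasis = "manufacturer_serve",
) -> NTSCGResult:
    """Traffic-light rating of a product under a declarative ruleset.

    First-match-wins over rule order; within the matched rule, any met
    condition triggers the override rating. Pure in (product, ruleset,
    basis); the returned explain record lists every condition evaluated.
    """
    if product.ntscg_exempt:
        raise ValueError(
            f"product {product.product_id} is NTSCG-exempt; exclude it upstream "
            "or use the sugar-inclusion scenario"
        )
    ruleset = ruleset or default_ntscg_ruleset()
    rule = ruleset.rule_for(product.ahs_minor_group)
    if rule is None:
        return NTSCGResult(rating=ruleset.default_rating, rule_id=None, conditions_evaluated=[])
    evaluated: list[tuple[str, bool]] = []
    any_met = False
    for cond in rule.conditions:
        met = cond.is_met(product, serving_basis)
        evaluated.append((cond.describe(), met))
        any_met = any_met or met
    rating = rule.if_met if (any_met and rule.if_met is not None) else rule.base
    return NTSCGResult(rating=rating, rule_id=rule.id, conditions_evaluated=evaluated)
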