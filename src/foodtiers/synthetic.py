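"""Synthetic retail catalog and sales generator.

The real study data — a year of remote-store sales linked to a
proprietary composition database — are not publicly available, so this
module generates datasets with the same statistical structure: a mix of
core and discretionary packaged products across AHS-style minor food
groups, per-100 g nutrition panels whose risk nutrients skew higher for
discretionary products, Health Star Ratings on the half-star grid that
correlate negatively with those risk nutrients, heavy-tailed store-level
sales quantities, sparse missing fields, and a small set of
system-exempt products (plain-sugar-like category).

A single latent healthiness score per product drives both the HSR and
the nutrient draws, so the three classification systems agree often but
not always — the regime in which the alignment analyses are
informative. The ``paperlike`` preset mirrors the analysed dataset's
scale: 4000 products, 51 stores, roughly half the products
discretionary.

Randomness uses numpy's seeded PCG64 generator; a fixed seed reproduces
the dataset bit-for-bit across platforms.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .records import CoreStatus, ProductRecord, SalesRecord

__all__ = [
    "CategoryNutrients",
    "HSRModel",
    "SalesModel",
    "MissingnessRates",
    "SimConfig",
    "paperlike_config",
    "generate_catalog",
    "generate_sales",
    "generate_sales_frame",
]


class CategoryNutrients(BaseModel):
    """Log-space location/scale for one category's per-100 g panel.

    ``added_share_core`` / ``added_share_disc`` are Beta(a, b) parameters
    for the added-to-total sugars ratio of core and discretionary
    products in the category.
    """

    energy: tuple[float, float]          # log kJ/100 g
    total_sugars: tuple[float, float]    # log g/100 g
    saturated_fat: tuple[float, float]   # log g/100 g
    sodium: tuple[float, float]          # log mg/100 g
    fibre: tuple[float, float] = (0.5, 0.5)
    net_weight: tuple[float, float] = (6.0, 0.3)  # log g
    added_share_core: tuple[float, float] = (1.5, 6.0)
    added_share_disc: tuple[float, float] = (6.0, 2.0)


class HSRModel(BaseModel):
    """Monotone map from the latent healthiness score to the star grid.

    ``hsr_raw = intercept + slope * z + N(0, noise_sd)`` snapped to the
    half-star grid and clipped to [0.5, 5]. ``core_shift`` is the mean
    latent-score advantage of core over discretionary products.
    """

    intercept: float = 2.75
    slope: float = 1.1
    noise_sd: float = Field(default=0.35, ge=0)
    core_shift: float = 0.9
    nutrient_slope: float = 0.25  # log-nutrient decrease per unit latent score


class SalesModel(BaseModel):
    """Heavy-tailed per-(product, store) quantities: zero-inflated
    log-normal, floored to integer units."""

    log_mean: float = 3.0
    log_sd: float = Field(default=1.5, ge=0)
    p_zero: float = Field(default=0.05, ge=0, le=1)


class MissingnessRates(BaseModel):
    """Per-product probabilities of absent fields (explicit ``None``)."""

    added_sugars: float = Field(default=0.010, ge=0, le=1)
    ingredient_flags: float = Field(default=0.004, ge=0, le=1)
    nutrition_panel: float = Field(default=0.003, ge=0, le=1)
    serving_size: float = Field(default=0.008, ge=0, le=1)


_DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "vegetables": 0.06,
    "fruit": 0.06,
    "bread": 0.07,
    "breakfast_cereal": 0.06,
    "dairy_milk": 0.06,
    "yoghurt": 0.04,
    "fruit_juice": 0.05,
    "fruit_drink": 0.04,
    "soft_drink": 0.12,
    "confectionery": 0.10,
    "snack_chips": 0.08,
    "pre_prepared_meal": 0.07,
    "savoury_pasta_noodle": 0.05,
    "pizza": 0.04,
    "biscuits": 0.06,
    "sugar": 0.02,
    "water": 0.02,
}

# Chosen so the overall discretionary share is ~49 % of products under
# the source-database flags.
_DEFAULT_P_DISC: dict[str, float] = {
    "vegetables": 0.0,
    "fruit": 0.0,
    "bread": 0.05,
    "breakfast_cereal": 0.30,
    "dairy_milk": 0.05,
    "yoghurt": 0.25,
    "fruit_juice": 0.0,
    "fruit_drink": 1.0,  # governs the ABS flag; source db calls these core
    "soft_drink": 1.0,
    "confectionery": 1.0,
    "snack_chips": 1.0,
    "pre_prepared_meal": 0.45,
    "savoury_pasta_noodle": 0.40,
    "pizza": 0.60,
    "biscuits": 1.0,
    "sugar": 1.0,
    "water": 0.0,
}

_DEFAULT_NUTRIENTS: dict[str, CategoryNutrients] = {
    "vegetables": CategoryNutrients(energy=(5.0, 0.4), total_sugars=(1.2, 0.5), saturated_fat=(-1.6, 0.5), sodium=(3.0, 0.8), fibre=(1.0, 0.4), net_weight=(6.0, 0.3)),
    "fruit": CategoryNutrients(energy=(5.5, 0.3), total_sugars=(2.3, 0.3), saturated_fat=(-2.0, 0.5), sodium=(1.5, 0.8), fibre=(0.8, 0.4), net_weight=(6.0, 0.3)),
    "bread": CategoryNutrients(energy=(6.9, 0.2), total_sugars=(1.5, 0.4), saturated_fat=(0.0, 0.4), sodium=(6.0, 0.25), fibre=(1.5, 0.4), net_weight=(6.5, 0.15)),
    "breakfast_cereal": CategoryNutrients(energy=(7.3, 0.12), total_sugars=(2.8, 0.5), saturated_fat=(0.2, 0.5), sodium=(5.5, 0.5), fibre=(2.0, 0.4), net_weight=(6.2, 0.25)),
    "dairy_milk": CategoryNutrients(energy=(5.6, 0.25), total_sugars=(1.6, 0.2), saturated_fat=(0.6, 0.5), sodium=(3.7, 0.3), fibre=(-2.0, 0.5), net_weight=(6.9, 0.3)),
    "yoghurt": CategoryNutrients(energy=(6.0, 0.25), total_sugars=(2.4, 0.4), saturated_fat=(0.9, 0.5), sodium=(4.0, 0.3), fibre=(-1.0, 0.5), net_weight=(5.1, 0.3)),
    "fruit_juice": CategoryNutrients(energy=(5.2, 0.2), total_sugars=(2.2, 0.25), saturated_fat=(-3.0, 0.5), sodium=(1.5, 0.8), fibre=(-1.0, 0.5), net_weight=(6.2, 0.5)),
    "fruit_drink": CategoryNutrients(energy=(5.0, 0.25), total_sugars=(2.4, 0.25), saturated_fat=(-3.0, 0.5), sodium=(2.0, 0.8), fibre=(-2.0, 0.5), net_weight=(6.2, 0.5)),
    "soft_drink": CategoryNutrients(energy=(5.2, 0.3), total_sugars=(2.35, 0.3), saturated_fat=(-4.0, 0.5), sodium=(2.5, 0.6), fibre=(-4.0, 0.5), net_weight=(6.1, 0.5)),
    "confectionery": CategoryNutrients(energy=(7.4, 0.15), total_sugars=(4.0, 0.2), saturated_fat=(1.5, 0.8), sodium=(4.0, 0.8), fibre=(0.0, 0.5), net_weight=(5.2, 0.4)),
    "snack_chips": CategoryNutrients(energy=(7.6, 0.1), total_sugars=(1.0, 0.6), saturated_fat=(1.8, 0.5), sodium=(6.3, 0.3), fibre=(1.3, 0.3), net_weight=(4.5, 0.4)),
    "pre_prepared_meal": CategoryNutrients(energy=(6.4, 0.3), total_sugars=(1.2, 0.5), saturated_fat=(1.2, 0.6), sodium=(6.0, 0.3), fibre=(0.5, 0.4), net_weight=(6.0, 0.2)),
    "savoury_pasta_noodle": CategoryNutrients(energy=(6.3, 0.3), total_sugars=(1.1, 0.5), saturated_fat=(1.3, 0.6), sodium=(6.0, 0.3), fibre=(0.7, 0.4), net_weight=(6.0, 0.2)),
    "pizza": CategoryNutrients(energy=(7.0, 0.15), total_sugars=(1.4, 0.4), saturated_fat=(1.5, 0.5), sodium=(6.2, 0.25), fibre=(0.8, 0.3), net_weight=(6.1, 0.2)),
    "biscuits": CategoryNutrients(energy=(7.5, 0.1), total_sugars=(3.2, 0.25), saturated_fat=(2.2, 0.4), sodium=(5.8, 0.3), fibre=(0.9, 0.3), net_weight=(5.5, 0.3)),
    "sugar": CategoryNutrients(energy=(7.4, 0.05), total_sugars=(4.55, 0.05), saturated_fat=(-4.0, 0.5), sodium=(0.5, 0.8), fibre=(-4.0, 0.5), net_weight=(6.9, 0.3)),
    "water": CategoryNutrients(energy=(-2.0, 0.5), total_sugars=(-3.0, 0.5), saturated_fat=(-5.0, 0.5), sodium=(2.0, 0.8), fibre=(-5.0, 0.5), net_weight=(6.4, 0.3)),
}

# Categories where added sugars are essentially absent regardless of flags.
_LOW_ADDED_SHARE = {"vegetables", "fruit", "fruit_juice", "water", "dairy_milk"}

_ARTIFICIAL_SWEETENER_P = {"soft_drink": 0.25, "water": 0.05, "fruit_drink": 0.10}
_CONFECTIONERY_P = {"confectionery": 1.0, "breakfast_cereal": 0.10, "yoghurt": 0.10}
_DEEP_FRIED_P = {"snack_chips": 0.50, "pre_prepared_meal": 0.15}


class SimConfig(BaseModel):
    """Full description of one synthetic dataset.

    Defaults are the ``paperlike`` study conditions: 4000 products, 51
    stores, ~49 % of products discretionary under the source-database
    flags, and the fruit-drink category carrying the core/discretionary
    discrepancy between the source database and the ABS flags.
    """

    n_products: int = Field(default=4000, ge=0)
    n_stores: int = Field(default=51, ge=0)
    category_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_CATEGORY_MIX))
    p_discretionary_by_category: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_P_DISC))
    nutrient_distributions: dict[str, CategoryNutrients] = Field(default_factory=lambda: dict(_DEFAULT_NUTRIENTS))
    hsr_model: HSRModel = Field(default_factory=HSRModel)
    sales_model: SalesModel = Field(default_factory=SalesModel)
    missingness_rates: MissingnessRates = Field(default_factory=MissingnessRates)
    exempt_rate: float = Field(default=0.002, ge=0, le=1)
    exempt_categories: set[str] = Field(default_factory=lambda: {"sugar"})
    discrepancy_categories: set[str] = Field(default_factory=lambda: {"fruit_drink"})
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "SimConfig":
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix proportions sum to {total}, not 1")
        for cat, p in self.p_discretionary_by_category.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_discretionary_by_category[{cat!r}] = {p} outside [0, 1]")
        for cat in self.category_mix:
            if cat not in self.p_discretionary_by_category:
                raise ValueError(f"category {cat!r} has no discretionary probability")
            if cat not in self.nutrient_distributions:
                raise ValueError(f"category {cat!r} has no nutrient distribution")
        return self


def paperlike_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions, optionally scaled via overrides."""
    return SimConfig(seed=seed, **overrides)


def _snap_half_star(x: float) -> float:
    return float(min(5.0, max(0.5, round(x * 2.0) / 2.0)))


def generate_catalog(config: SimConfig) -> list[ProductRecord]:
    """Draw a validated product catalog; deterministic given ``config.seed``."""
    rng = np.random.default_rng([config.seed, 1])
    categories = sorted(config.category_mix)
    probs = np.array([config.category_mix[c] for c in categories])
    probs = probs / probs.sum()
    hm = config.hsr_model

    products: list[ProductRecord] = []
    for i in range(config.n_products):
        cat = categories[rng.choice(len(categories), p=probs)]
        nut = config.nutrient_distributions[cat]
        p_disc = config.p_discretionary_by_category[cat]
        disc = bool(rng.random() < p_disc)
        if cat in config.discrepancy_categories:
            # emulates fruit drinks: core in the source database,
            # discretionary under ABS principles
            core_source = CoreStatus.CORE
            core_abs = CoreStatus.DISCRETIONARY
        else:
            core_source = CoreStatus.DISCRETIONARY if disc else CoreStatus.CORE
            core_abs = core_source

        z = (hm.core_shift if core_source is CoreStatus.CORE else -hm.core_shift) + rng.normal()
        hsr = _snap_half_star(hm.intercept + hm.slope * z + rng.normal(0, hm.noise_sd))

        def draw(mu_sigma: tuple[float, float], slope_sign: float = -1.0) -> float:
            mu, sigma = mu_sigma
            return float(np.exp(mu + slope_sign * hm.nutrient_slope * z + rng.normal(0, sigma)))

        energy = round(draw(nut.energy), 1)
        total_sugars = min(100.0, round(draw(nut.total_sugars), 2))
        saturated_fat = min(100.0, round(draw(nut.saturated_fat), 2))
        sodium = round(draw(nut.sodium), 1)
        fibre = round(draw(nut.fibre, slope_sign=+0.8), 2)
        if cat in _LOW_ADDED_SHARE:
            share = float(rng.beta(1.0, 30.0))
        elif core_source is CoreStatus.DISCRETIONARY or core_abs is CoreStatus.DISCRETIONARY:
            share = float(rng.beta(*nut.added_share_disc))
        else:
            share = float(rng.beta(*nut.added_share_core))
        added_sugars = min(round(share * total_sugars, 2), total_sugars)

        net_weight = round(draw(nut.net_weight, slope_sign=0.0), 0)
        net_weight = max(net_weight, 10.0)
        serving_size = round(net_weight * rng.uniform(0.15, 1.0), 0)
        serving_size = min(max(serving_size, 1.0), net_weight)

        if cat == "fruit_juice":
            pct_juice = round(float(rng.uniform(99, 100)) if rng.random() < 0.8 else float(rng.uniform(30, 98)), 1)
        elif cat == "fruit_drink":
            pct_juice = round(float(rng.uniform(5, 35)), 1)
        else:
            pct_juice = 0.0

        artificially_sweetened = bool(rng.random() < _ARTIFICIAL_SWEETENER_P.get(cat, 0.0))
        contains_confectionery = bool(rng.random() < _CONFECTIONERY_P.get(cat, 0.0))
        deep_fried = bool(rng.random() < _DEEP_FRIED_P.get(cat, 0.0))

        exempt = cat in config.exempt_categories or bool(rng.random() < config.exempt_rate)

        mr = config.missingness_rates
        fields: dict[str, object] = dict(
            product_id=f"P{i:06d}",
            description=f"{cat} product {i}",
            net_weight=net_weight,
            serving_size=serving_size,
            package_size=net_weight,
            energy=energy,
            saturated_fat=saturated_fat,
            total_sugars=total_sugars,
            added_sugars=added_sugars,
            sodium=sodium,
            fibre=fibre,
            pct_fruit_veg_juice=pct_juice,
            artificially_sweetened=artificially_sweetened,
            contains_confectionery=contains_confectionery,
            deep_fried=deep_fried,
            hsr=hsr,
            core_source_db=core_source,
            core_abs=core_abs,
            ahs_minor_group=cat,
            source_db_category=cat,
            hsr_exempt=exempt,
            ntscg_exempt=exempt,
        )
        if rng.random() < mr.added_sugars:
            fields["added_sugars"] = None
        if rng.random() < mr.ingredient_flags:
            fields["artificially_sweetened"] = None
            fields["contains_confectionery"] = None
            fields["deep_fried"] = None
        if rng.random() < mr.nutrition_panel:
            fields["sodium"] = None
            fields["saturated_fat"] = None
        if rng.random() < mr.serving_size:
            fields["serving_size"] = None
        products.append(ProductRecord(**fields))
    return products


def generate_sales_frame(catalog: list[ProductRecord], config: SimConfig) -> pd.DataFrame:
    """Per-(product, store) quantities as a DataFrame; one row per pair."""
    n_p, n_s = len(catalog), config.n_stores
    rng = np.random.default_rng([config.seed, 2])
    sm = config.sales_model
    raw = np.exp(rng.normal(sm.log_mean, sm.log_sd, size=(n_p, n_s)))
    quantities = np.floor(raw).astype("int64")
    if sm.p_zero > 0:
        quantities[rng.random(size=(n_p, n_s)) < sm.p_zero] = 0
    product_ids = np.repeat(np.array([p.product_id for p in catalog], dtype=object), n_s)
    store_ids = np.tile(np.array([f"S{j:03d}" for j in range(n_s)], dtype=object), n_p)
    return pd.DataFrame(
        {"product_id": product_ids, "store_id": store_ids, "quantity_sold": quantities.ravel()}
    )


def generate_sales(catalog: list[ProductRecord], config: SimConfig) -> list[SalesRecord]:
    """Validated sales records, one per (product, store) pair."""
    frame = generate_sales_frame(catalog, config)
    return [
        SalesRecord(product_id=r.product_id, store_id=r.store_id, quantity_sold=int(r.quantity_sold))
        for r in frame.itertuples(index=False)
    ]
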