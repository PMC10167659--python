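"""Sales-weighted primary outcomes.

Two quantities summarise what a product contributes to the community
diet over the study window:

* **discretionary energy sold** (kJ) = net weight (g) x units sold x
  energy (kJ/100 g) / 100, for products whose governing core flag is
  discretionary; structurally zero for core products;
* **added sugars sold** (g) = net weight (g) x units sold x estimated
  added sugars (g/100 g) / 100, for every product.

Both scale linearly in quantity sold. The per-product unit factor
(net weight x panel value / 100) is computed once, so the store-level
decomposition — integer quantities summed exactly, then multiplied —
matches the aggregated analysis bit-for-bit.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .io import LinkedDataset
from .records import CoreStatus

__all__ = ["compute_outcomes", "compute_outcomes_store_level"]

OUTCOME_COLUMNS = ("quantity_sold", "discretionary_energy_sold", "added_sugars_sold")


def _unit_factors(linked: LinkedDataset, core_source: str) -> pd.DataFrame:
    rows = []
    for p in linked.products:
        if p.net_weight is None or p.energy is None or p.added_sugars is None:
            raise ValueError(
                f"product {p.product_id} is missing net_weight, energy or added_sugars; "
                "it should have been excluded at the linkage stage"
            )
        status = p.core_status(core_source)
        if status is None:
            raise ValueError(f"product {p.product_id} has no {core_source} core flag")
        disc = status is CoreStatus.DISCRETIONARY
        rows.append(
            {
                "product_id": p.product_id,
                "energy_per_unit": p.net_weight * p.energy / 100.0 if disc else 0.0,
                "added_sugars_per_unit": p.net_weight * p.added_sugars / 100.0,
            }
        )
    return pd.DataFrame(rows).set_index("product_id")


def compute_outcomes(linked: LinkedDataset, core_source: str = "source_db") -> pd.DataFrame:
    """Per-product outcome weights, quantities summed over stores.

    Returns a frame indexed by ``product_id`` with columns
    ``quantity_sold``, ``discretionary_energy_sold`` (kJ) and
    ``added_sugars_sold`` (g).
    """
    factors = _unit_factors(linked, core_source)
    quantity = linked.quantity.reindex(factors.index).fillna(0).astype("int64")
    out = pd.DataFrame(index=factors.index)
    out["quantity_sold"] = quantity
    out["discretionary_energy_sold"] = factors["energy_per_unit"] * quantity
    out["added_sugars_sold"] = factors["added_sugars_per_unit"] * quantity
    return out


def compute_outcomes_store_level(
    linked: LinkedDataset, core_source: str = "source_db"
) -> pd.DataFrame:
    """Outcome weights per (product, store) before any aggregation."""
    factors = _unit_factors(linked, core_source)
    sales = linked.sales
    out = sales[["product_id", "store_id", "quantity_sold"]].copy()
    out["discretionary_energy_sold"] = (
        factors["energy_per_unit"].reindex(out["product_id"]).to_numpy() * out["quantity_sold"].to_numpy()
    )
    out["added_sugars_sold"] = (
        factors["added_sugars_per_unit"].reindex(out["product_id"]).to_numpy()
        * out["quantity_sold"].to_numpy()
    )
    return out
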