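"""Sensitivity analyses around the main three-system comparison.

Three scenarios, each perturbing exactly one factor:

* **store level** — outcomes and performance recomputed per store
  (distribution of per-store capture percentages, summarised as median
  and interquartile range) alongside the pooled result, which equals
  the aggregated main analysis exactly because integer quantities are
  summed before the per-product weight factor is applied;
* **serving basis** — NTSCG per-serve criteria re-evaluated against
  total package size instead of the manufacturer serve;
* **sugar inclusion** — system-exempt plain-sugar products re-admitted
  with their HSR and an NTSCG rating forced to Red, as they sit outside
  both the HSR and the NTSCG.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import WEIGHT_LAYERS, Tier, performance
from .analysis import AnalysisConfig, MainResult, analyse_tiers, classify_all, main_analysis
from .io import ExclusionConfig, LinkedDataset, link_and_filter, sales_to_frame
from .outcomes import compute_outcomes
from .records import ProductRecord, SalesRecord

__all__ = [
    "SensitivityReport",
    "StoreLevelSummary",
    "store_level_run",
    "serving_basis_run",
    "sugar_inclusion_run",
    "alignment_summary",
    "summary_deltas",
]


def alignment_summary(result: MainResult) -> dict:
    """Flat summary of a main-analysis result: congruence and extreme
    disagreement per system pair and layer, plus per-system captures."""
    out: dict = {"congruence": {}, "extreme": {}, "capture": {}}
    for pair, matrix in result.matrices.items():
        key = "_vs_".join(pair)
        out["congruence"][key] = {
            layer: matrix.diagonal_pct(layer) for layer in WEIGHT_LAYERS
        }
        out["extreme"][key] = dict(result.extreme[pair])
    for name, perf in result.performance.systems.items():
        out["capture"][name] = {
            "unhealthy_discretionary_energy": perf.capture("discretionary_energy", Tier.UNHEALTHY),
            "unhealthy_added_sugars": perf.capture("added_sugars", Tier.UNHEALTHY),
            "healthy_discretionary_energy": perf.capture("discretionary_energy", Tier.HEALTHY),
            "healthy_added_sugars": perf.capture("added_sugars", Tier.HEALTHY),
        }
    return out


def _delta(a, b):
    if isinstance(a, dict) and isinstance(b, dict):
        return {k: _delta(a[k], b[k]) for k in a}
    if a is None or b is None:
        return None
    return a - b


def summary_deltas(scenario: MainResult, main: MainResult) -> dict:
    """Scenario-minus-main deltas of the flat alignment summary."""
    return _delta(alignment_summary(scenario), alignment_summary(main))


@dataclasses.dataclass
class StoreLevelSummary:
    """Distribution of per-store capture percentages.

    ``per_store[store][system][metric]`` is a percentage or ``None``
    when that store's weight base is zero; ``summary[system][metric]``
    is (median, 25th, 75th percentile) over the defined stores.
    """

    per_store: dict[str, dict[str, dict[str, Optional[float]]]]
    summary: dict[str, dict[str, tuple[float, float, float]]]
    n_stores: int


@dataclasses.dataclass
class SensitivityReport:
    scenario: str
    main: MainResult
    result: MainResult
    deltas: dict
    store_summary: Optional[StoreLevelSummary] = None
    notes: dict = dataclasses.field(default_factory=dict)


_CAPTURE_METRICS = {
    "unhealthy_discretionary_energy": ("discretionary_energy", Tier.UNHEALTHY),
    "unhealthy_added_sugars": ("added_sugars", Tier.UNHEALTHY),
    "healthy_discretionary_energy": ("discretionary_energy", Tier.HEALTHY),
    "healthy_added_sugars": ("added_sugars", Tier.HEALTHY),
}


def store_level_run(
    linked: LinkedDataset, config: Optional[AnalysisConfig] = None
) -> SensitivityReport:
    """Repeat the performance analysis store by store.

    Tier assignments do not vary by store, so per-store variation comes
    entirely from the sales weights. The pooled result is the main
    analysis itself: quantities are integers and are summed per product
    before the weight factor is applied.
    """
    config = config or AnalysisConfig()
    main = main_analysis(linked, config)
    tiers = main.tiers.by_system()

    per_store: dict[str, dict[str, dict[str, Optional[float]]]] = {}
    stores = sorted(linked.sales["store_id"].unique())
    for store in stores:
        store_sales = linked.sales[linked.sales["store_id"] == store]
        store_linked = LinkedDataset(
            products=linked.products,
            sales=store_sales.reset_index(drop=True),
            quantity=store_sales.groupby("product_id")["quantity_sold"]
            .sum()
            .reindex([p.product_id for p in linked.products])
            .fillna(0)
            .astype("int64"),
        )
        outcomes = compute_outcomes(store_linked, config.core_source)
        report = performance(tiers, outcomes)
        per_store[store] = {
            system: {
                metric: perf.capture(layer, tier)
                for metric, (layer, tier) in _CAPTURE_METRICS.items()
            }
            for system, perf in report.systems.items()
        }

    summary: dict[str, dict[str, tuple[float, float, float]]] = {}
    for system in ("thumbs", "hsr", "ntscg"):
        summary[system] = {}
        for metric in _CAPTURE_METRICS:
            values = [
                per_store[s][system][metric]
                for s in stores
                if per_store[s][system][metric] is not None
            ]
            if values:
                med, q1, q3 = (
                    float(np.median(values)),
                    float(np.percentile(values, 25)),
                    float(np.percentile(values, 75)),
                )
                summary[system][metric] = (med, q1, q3)
    store_summary = StoreLevelSummary(per_store=per_store, summary=summary, n_stores=len(stores))
    return SensitivityReport(
        scenario="store_level",
        main=main,
        result=main,  # pooled result is identical to the aggregated analysis
        deltas=summary_deltas(main, main),
        store_summary=store_summary,
    )


def serving_basis_run(
    linked: LinkedDataset, config: Optional[AnalysisConfig] = None
) -> SensitivityReport:
    """Re-run the analysis with NTSCG per-serve criteria on package size."""
    config = config or AnalysisConfig()
    main = main_analysis(linked, config)
    alt_config = dataclasses.replace(config, serving_basis="package_size")
    scenario = main_analysis(linked, alt_config)
    return SensitivityReport(
        scenario="serving_basis",
        main=main,
        result=scenario,
        deltas=summary_deltas(scenario, main),
    )


def sugar_inclusion_run(
    catalog: Sequence[ProductRecord],
    sales: Sequence[SalesRecord] | pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    exclusion_config: Optional[ExclusionConfig] = None,
    sugar_categories: frozenset[str] = frozenset({"sugar"}),
) -> SensitivityReport:
    """Re-admit exempt sugar-category products with NTSCG forced to Red.

    Sugar products must carry an HSR for this scenario (they are
    HSR-exempt in the main analysis but rateable in principle); a
    missing HSR raises, listing the offending products.
    """
    config = config or AnalysisConfig()
    sales_frame = sales if isinstance(sales, pd.DataFrame) else sales_to_frame(sales)
    linked_main, _ = link_and_filter(catalog, sales_frame, exclusion_config)
    main = main_analysis(linked_main, config)

    sugar_exempt = [
        p
        for p in catalog
        if p.ahs_minor_group in sugar_categories and (p.hsr_exempt or p.ntscg_exempt)
    ]
    missing_hsr = [p.product_id for p in sugar_exempt if p.hsr is None]
    if missing_hsr:
        raise ValueError(
            f"sugar products without an HSR cannot enter this scenario: {missing_hsr}"
        )

    readmit_ids = {p.product_id for p in sugar_exempt}
    adjusted = [
        p.model_copy(update={"hsr_exempt": False, "ntscg_exempt": False})
        if p.product_id in readmit_ids
        else p
        for p in catalog
    ]
    linked_scenario, _ = link_and_filter(adjusted, sales_frame, exclusion_config)
    tiers = classify_all(linked_scenario, config)
    forced = readmit_ids & set(tiers.ntscg)
    for pid in forced:
        tiers.ntscg[pid] = Tier.UNHEALTHY  # exempt sugar products assumed Red
    scenario = analyse_tiers(linked_scenario, tiers, config)
    return SensitivityReport(
        scenario="sugar_inclusion",
        main=main,
        result=scenario,
        deltas=summary_deltas(scenario, main),
        notes={"n_sugar_products_readmitted": len(forced)},
    )
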