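"""Full pipeline: link/filter -> classify -> outcomes -> alignment ->
performance -> modifications -> sensitivity, with a serialisable report
bundle. Identical config and inputs produce byte-identical JSON output.
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from .alignment import TIER_DISPLAY, WEIGHT_LAYERS, AlignmentMatrix, PerformanceReport
from .analysis import AnalysisConfig, MainResult, analyse_tiers, classify_all, main_analysis
from .classifiers import (
    HSRTierBoundaries,
    NTSCGRuleSet,
    ThumbsRuleTable,
    default_ntscg_ruleset,
)
from .io import ExclusionConfig, ExclusionReport, link_and_filter, read_catalog, read_sales
from .modifications import (
    DEFAULT_OVERLAY_CATEGORIES,
    BaseThumbsClassifier,
    apply_abs_core_flags,
    apply_ntscg_overlay,
    compare_pre_post,
    rank_misalignment_sources,
)
from .classifiers import map_to_tier
from .sensitivity import serving_basis_run, store_level_run, sugar_inclusion_run
from .synthetic import SimConfig, generate_catalog, generate_sales_frame

__all__ = ["RunConfig", "run_pipeline", "format_pct"]

log = logging.getLogger("foodtiers")


def format_pct(value: Optional[float]) -> str:
    """One-decimal, half-up percentage for presentation output."""
    if value is None:
        return "NA"
    return str(decimal.Decimal(repr(value)).quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


class RunConfig(BaseModel):
    """Configuration of one full pipeline run.

    When ``catalog_path``/``sales_path`` are unset, a synthetic dataset
    is generated from ``sim`` (the paperlike preset by default, with
    ``seed`` applied).
    """

    catalog_path: Optional[str] = None
    sales_path: Optional[str] = None
    ruleset_path: Optional[str] = None
    thumbs_table_path: Optional[str] = None
    output_dir: Optional[str] = None
    core_source: str = "source_db"
    serving_basis: str = "manufacturer_serve"
    hsr_boundaries: HSRTierBoundaries = Field(default_factory=HSRTierBoundaries)
    exclusions: ExclusionConfig = Field(default_factory=ExclusionConfig)
    overlay_categories: list[str] = Field(default_factory=lambda: list(DEFAULT_OVERLAY_CATEGORIES))
    scenarios: list[str] = Field(default_factory=lambda: ["store_level", "serving_basis", "sugar_inclusion"])
    sim: SimConfig = Field(default_factory=SimConfig)
    seed: int = 0
    log_level: str = "INFO"


def _matrix_dict(matrix: AlignmentMatrix) -> dict:
    names = [t.name for t in TIER_DISPLAY]
    return {
        "systems": list(matrix.system_pair),
        "n_products": matrix.n_products,
        "tiers": names,
        "counts": matrix.counts.tolist(),
        "pct": {
            layer: (None if matrix.pct[layer] is None else matrix.pct[layer].tolist())
            for layer in WEIGHT_LAYERS
        },
        "congruence_pct": {layer: matrix.diagonal_pct(layer) for layer in WEIGHT_LAYERS},
    }


def _tier_dist_dict(dist: dict) -> dict:
    return {
        layer: (None if dist[layer] is None else {t.name: dist[layer][t] for t in TIER_DISPLAY})
        for layer in WEIGHT_LAYERS
    }


def _performance_dict(report: PerformanceReport) -> dict:
    out: dict = {"systems": {}, "best_performing": report.best_performing}
    for name, perf in report.systems.items():
        out["systems"][name] = {
            "pct_per_tier": {
                layer: (
                    None
                    if perf.pct[layer] is None
                    else {t.name: perf.pct[layer][t] for t in TIER_DISPLAY}
                )
                for layer in WEIGHT_LAYERS
            },
            "healthy_energy_structural_zero": perf.healthy_energy_structural_zero,
        }
    return out


def _main_result_dict(result: MainResult) -> dict:
    kappa = result.kappa_thumbs_ntscg
    return {
        "matrices": { "_vs_".join(pair): _matrix_dict(m) for pair, m in result.matrices.items()},
        "extreme_disagreement": {
            "_vs_".join(pair): dict(e) for pair, e in result.extreme.items()
        },
        "kappa_thumbs_vs_ntscg": {
            "kappa": kappa.kappa,
            "p_observed": kappa.p_observed,
            "p_expected": kappa.p_expected,
            "contingency": kappa.contingency.tolist(),
            "band": kappa.band,
            "note": kappa.note,
        },
        "performance": _performance_dict(result.performance),
    }


def _exclusion_dict(report: ExclusionReport) -> dict:
    return {
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "n_excluded_by_reason": dict(report.n_excluded_by_reason),
        "excluded_share_of_quantity": report.excluded_share_of_quantity,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis end to end.

    Returns the report bundle as a JSON-serialisable dict; when
    ``output_dir`` is set, writes ``report.json`` plus delimited summary
    tables there.
    """
    logging.basicConfig(level=config.log_level)

    if config.catalog_path and config.sales_path:
        log.info("stage=load catalog=%s sales=%s", config.catalog_path, config.sales_path)
        catalog = read_catalog(config.catalog_path)
        sales = read_sales(config.sales_path)
    else:
        sim = config.sim.model_copy(update={"seed": config.seed})
        log.info("stage=simulate n_products=%d n_stores=%d seed=%d", sim.n_products, sim.n_stores, sim.seed)
        catalog = generate_catalog(sim)
        sales = generate_sales_frame(catalog, sim)

    analysis_config = AnalysisConfig(
        thumbs_table=(
            ThumbsRuleTable.from_yaml(config.thumbs_table_path)
            if config.thumbs_table_path
            else ThumbsRuleTable()
        ),
        hsr_boundaries=config.hsr_boundaries,
        ruleset=(
            NTSCGRuleSet.from_yaml(config.ruleset_path)
            if config.ruleset_path
            else default_ntscg_ruleset()
        ),
        core_source=config.core_source,
        serving_basis=config.serving_basis,  # type: ignore[arg-type]
    )

    linked, exclusion = link_and_filter(catalog, sales, config.exclusions)
    log.info(
        "stage=link n_input=%d n_retained=%d excluded=%s",
        exclusion.n_input,
        exclusion.n_retained,
        exclusion.n_excluded_by_reason,
    )

    main = main_analysis(linked, analysis_config)
    log.info(
        "stage=align congruence(products)=%s kappa=%s",
        {"_vs_".join(p): m.diagonal_pct("products") for p, m in main.matrices.items()},
        main.kappa_thumbs_ntscg.kappa,
    )

    # modifications
    misalignment = rank_misalignment_sources(linked, main.tiers.thumbs, main.tiers.ntscg, main.outcomes)
    base = BaseThumbsClassifier(analysis_config.thumbs_table, analysis_config.core_source)
    overlay_targets = [
        c for c in config.overlay_categories if c in analysis_config.ruleset.matched_categories()
    ]
    overlay = apply_ntscg_overlay(base, analysis_config.ruleset, overlay_targets)
    overlay_tiers = {
        p.product_id: map_to_tier(overlay.classify(p)) for p in linked.products
    }
    overlay_report = compare_pre_post(
        main.tiers.thumbs, overlay_tiers, main.outcomes, name="ntscg_overlay", check_direction=True
    )
    log.info("stage=modify overlay_reclassified=%d", overlay_report.n_reclassified)

    _, flag_comparison = apply_abs_core_flags(linked)
    abs_config = dataclasses.replace(analysis_config, core_source="abs")
    abs_tiers_full = classify_all(linked, abs_config)
    # deltas measured against the main outcome weights so the layers compare like with like
    abs_report = compare_pre_post(
        main.tiers.thumbs, abs_tiers_full.thumbs, main.outcomes, name="abs_core_flags"
    )
    log.info(
        "stage=modify abs_discordant=%d share=%.2f%%",
        flag_comparison.n_discordant,
        flag_comparison.discordant_share,
    )

    bundle: dict = {
        "config": json.loads(config.model_dump_json()),
        "exclusion": _exclusion_dict(exclusion),
        "main": _main_result_dict(main),
        "misalignment_sources": {
            "n_misaligned": misalignment.n_misaligned,
            "entries": [
                {"category": c, "added_sugars_sold": s, "share_pct": pct}
                for c, s, pct in misalignment.entries
            ],
        },
        "modifications": {
            "ntscg_overlay": {
                "n_reclassified": overlay_report.n_reclassified,
                "direction_ok": overlay_report.direction_ok,
                "pre": _tier_dist_dict(overlay_report.pre),
                "post": _tier_dist_dict(overlay_report.post),
                "delta": _tier_dist_dict(overlay_report.delta),
            },
            "abs_core_flags": {
                "n_discordant": flag_comparison.n_discordant,
                "discordant_share_pct": flag_comparison.discordant_share,
                "n_reclassified": abs_report.n_reclassified,
                "pre": _tier_dist_dict(abs_report.pre),
                "post": _tier_dist_dict(abs_report.post),
                "delta": _tier_dist_dict(abs_report.delta),
            },
        },
        "sensitivity": {},
    }

    for scenario in config.scenarios:
        log.info("stage=sensitivity scenario=%s", scenario)
        if scenario == "store_level":
            rep = store_level_run(linked, analysis_config)
            bundle["sensitivity"][scenario] = {
                "deltas": rep.deltas,
                "per_store_summary": rep.store_summary.summary if rep.store_summary else None,
                "n_stores": rep.store_summary.n_stores if rep.store_summary else 0,
            }
        elif scenario == "serving_basis":
            rep = serving_basis_run(linked, analysis_config)
            bundle["sensitivity"][scenario] = {"deltas": rep.deltas}
        elif scenario == "sugar_inclusion":
            rep = sugar_inclusion_run(catalog, sales if isinstance(sales, pd.DataFrame) else sales, analysis_config, config.exclusions)
            bundle["sensitivity"][scenario] = {"deltas": rep.deltas, "notes": rep.notes}
        else:
            raise ValueError(f"unknown sensitivity scenario {scenario!r}")

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        _write_tables(bundle, out)
        log.info("stage=write output_dir=%s", out)
    return bundle


def _write_tables(bundle: dict, out: Path) -> None:
    rows = []
    for system, payload in bundle["main"]["performance"]["systems"].items():
        for layer, per_tier in payload["pct_per_tier"].items():
            if per_tier is None:
                continue
            for tier, value in per_tier.items():
                shown = value
                if (
                    payload["healthy_energy_structural_zero"]
                    and layer == "discretionary_energy"
                    and tier == "HEALTHY"
                ):
                    rows.append({"system": system, "layer": layer, "tier": tier, "pct": "NA"})
                    continue
                rows.append(
                    {"system": system, "layer": layer, "tier": tier, "pct": format_pct(shown)}
                )
    pd.DataFrame(rows).to_csv(out / "performance.csv", index=False)

    rows = []
    for pair, payload in bundle["main"]["matrices"].items():
        for layer, pct in payload["congruence_pct"].items():
            rows.append({"pair": pair, "layer": layer, "congruence_pct": format_pct(pct)})
    pd.DataFrame(rows).to_csv(out / "congruence.csv", index=False)
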