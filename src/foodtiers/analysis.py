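"""End-to-end analysis helpers shared by the pipeline, the sensitivity
scenarios and the CLI: classify every retained product under all three
systems and assemble the full alignment/performance result."""

from __future__ import annotations

import dataclasses
from typing import Optional

import pandas as pd

from .alignment import (
    AgreementResult,
    AlignmentMatrix,
    PerformanceReport,
    cohens_kappa,
    crosstab,
    extreme_disagreement,
    performance,
)
from .classifiers import (
    HSRTierBoundaries,
    NTSCGRuleSet,
    ServingBasis,
    ThumbsRuleTable,
    Tier,
    classify_hsr_tier,
    classify_ntscg,
    classify_thumbs,
    default_ntscg_ruleset,
    map_to_tier,
)
from .io import LinkedDataset
from .outcomes import compute_outcomes

__all__ = [
    "AnalysisConfig",
    "TierAssignments",
    "MainResult",
    "classify_all",
    "analyse_tiers",
    "main_analysis",
]

SYSTEMS = ("thumbs", "hsr", "ntscg")


@dataclasses.dataclass
class AnalysisConfig:
    """Everything the classification and comparison stages depend on."""

    thumbs_table: ThumbsRuleTable = dataclasses.field(default_factory=ThumbsRuleTable)
    hsr_boundaries: HSRTierBoundaries = dataclasses.field(default_factory=HSRTierBoundaries)
    ruleset: NTSCGRuleSet = dataclasses.field(default_factory=default_ntscg_ruleset)
    core_source: str = "source_db"
    serving_basis: ServingBasis = "manufacturer_serve"


@dataclasses.dataclass
class TierAssignments:
    """Tier of every retained product under each system, plus the raw
    Thumbs and NTSCG ratings behind them."""

    thumbs: dict[str, Tier]
    hsr: dict[str, Tier]
    ntscg: dict[str, Tier]
    thumbs_rating: dict[str, object]
    ntscg_rating: dict[str, object]

    def by_system(self) -> dict[str, dict[str, Tier]]:
        return {"thumbs": self.thumbs, "hsr": self.hsr, "ntscg": self.ntscg}


def classify_all(linked: LinkedDataset, config: Optional[AnalysisConfig] = None) -> TierAssignments:
    """Run all three classifiers over the retained products."""
    config = config or AnalysisConfig()
    thumbs: dict[str, Tier] = {}
    hsr: dict[str, Tier] = {}
    ntscg: dict[str, Tier] = {}
    thumbs_rating: dict[str, object] = {}
    ntscg_rating: dict[str, object] = {}
    for product in linked.products:
        rating = classify_thumbs(product, config.thumbs_table, config.core_source)
        thumbs_rating[product.product_id] = rating
        thumbs[product.product_id] = map_to_tier(rating)
        hsr[product.product_id] = classify_hsr_tier(product.hsr, config.hsr_boundaries)
        result = classify_ntscg(product, config.ruleset, config.serving_basis)
        ntscg_rating[product.product_id] = result.rating
        ntscg[product.product_id] = result.tier
    return TierAssignments(
        thumbs=thumbs, hsr=hsr, ntscg=ntscg, thumbs_rating=thumbs_rating, ntscg_rating=ntscg_rating
    )


@dataclasses.dataclass
class MainResult:
    """The full alignment/performance analysis on one linked dataset."""

    tiers: TierAssignments
    outcomes: pd.DataFrame
    matrices: dict[tuple[str, str], AlignmentMatrix]
    extreme: dict[tuple[str, str], dict[str, Optional[float]]]
    kappa_thumbs_ntscg: AgreementResult
    performance: PerformanceReport


def analyse_tiers(
    linked: LinkedDataset, tiers: TierAssignments, config: Optional[AnalysisConfig] = None
) -> MainResult:
    """Alignment/performance statistics for precomputed tier assignments.

    Cohen's kappa is computed for Thumbs vs NTSCG only; Thumbs and HSR
    share the HSR input and are not independent raters.
    """
    config = config or AnalysisConfig()
    outcomes = compute_outcomes(linked, config.core_source)
    pairs = [("thumbs", "hsr"), ("thumbs", "ntscg"), ("hsr", "ntscg")]
    by_system = tiers.by_system()
    matrices = {
        pair: crosstab(by_system[pair[0]], by_system[pair[1]], outcomes, system_pair=pair)
        for pair in pairs
    }
    extreme = {pair: extreme_disagreement(m) for pair, m in matrices.items()}
    ids = sorted(tiers.thumbs)
    kappa = cohens_kappa(
        [tiers.thumbs[i] is Tier.HEALTHY for i in ids],
        [tiers.ntscg[i] is Tier.HEALTHY for i in ids],
    )
    report = performance(by_system, outcomes)
    return MainResult(
        tiers=tiers,
        outcomes=outcomes,
        matrices=matrices,
        extreme=extreme,
        kappa_thumbs_ntscg=kappa,
        performance=report,
    )


def main_analysis(linked: LinkedDataset, config: Optional[AnalysisConfig] = None) -> MainResult:
    """Classify every retained product, then cross-tabulate and rank."""
    config = config or AnalysisConfig()
    return analyse_tiers(linked, classify_all(linked, config), config)
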