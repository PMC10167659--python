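"""Modelled modifications to the Thumbs algorithm.

Two optimisations are modelled, motivated by where added sugars leak
into the Thumbs healthy tier:

1. **NTSCG-criteria overlay** — for a target set of food categories
   (breakfast cereals, fruit/vegetable juices and drinks, pre-prepared
   meals including pizza and savoury pasta/noodle dishes), a product
   whose NTSCG traffic light maps to a *lower* tier than its Thumbs
   rating is demoted to the worst Thumbs rating inside that lower tier.
   Products are never promoted, and categories outside the target set
   are untouched.
2. **ABS core/discretionary realignment** — the Thumbs classifier is
   switched from the composition database's core flags to the AHS/ABS
   flags, which reclassifies the discordant-flag products (in practice
   fruit-drink-like items that the source database calls core).

:func:`compare_pre_post` quantifies either modification as pre/post
tier distributions and their deltas over the three weight bases.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional, Protocol, Sequence

import pandas as pd

from .alignment import TIER_DISPLAY, WEIGHT_LAYERS
from .classifiers import (
    NTSCGRuleSet,
    ServingBasis,
    ThumbsRating,
    ThumbsRuleTable,
    Tier,
    classify_ntscg,
    classify_thumbs,
    map_to_tier,
)
from .io import LinkedDataset
from .records import CoreStatus, ProductRecord

__all__ = [
    "MisalignmentSourceReport",
    "ModificationReport",
    "CoreFlagComparison",
    "ThumbsClassifier",
    "BaseThumbsClassifier",
    "OverlayThumbsClassifier",
    "rank_misalignment_sources",
    "apply_ntscg_overlay",
    "apply_abs_core_flags",
    "compare_pre_post",
]


class ThumbsClassifier(Protocol):
    def classify(self, product: ProductRecord) -> ThumbsRating: ...


@dataclasses.dataclass
class BaseThumbsClassifier:
    """The unmodified Thumbs algorithm as a classifier object."""

    table: ThumbsRuleTable = dataclasses.field(default_factory=ThumbsRuleTable)
    core_source: str = "source_db"

    def classify(self, product: ProductRecord) -> ThumbsRating:
        return classify_thumbs(product, self.table, self.core_source)


#: Worst Thumbs rating inside each tier — the demotion target.
_WORST_IN_TIER = {
    Tier.SOMEWHAT_HEALTHY: ThumbsRating.SIDEWAYS,
    Tier.UNHEALTHY: ThumbsRating.DOWN,
}


@dataclasses.dataclass
class OverlayThumbsClassifier:
    """Thumbs classifier with NTSCG criteria overlaid on target categories.

    Demotion-only: within the target categories, if the NTSCG rating
    maps to a lower tier than the inner Thumbs rating, the product is
    demoted to the worst Thumbs rating in the NTSCG tier; otherwise the
    inner rating stands. Idempotent by construction.
    """

    inner: ThumbsClassifier
    ruleset: NTSCGRuleSet
    target_categories: frozenset[str]
    serving_basis: ServingBasis = "manufacturer_serve"

    def classify(self, product: ProductRecord) -> ThumbsRating:
        rating = self.inner.classify(product)
        if product.ahs_minor_group not in self.target_categories:
            return rating
        ntscg_tier = classify_ntscg(product, self.ruleset, self.serving_basis).tier
        if ntscg_tier < map_to_tier(rating):
            return _WORST_IN_TIER[ntscg_tier]
        return rating


def apply_ntscg_overlay(
    thumbs: ThumbsClassifier,
    ruleset: NTSCGRuleSet,
    target_categories: Sequence[str],
) -> OverlayThumbsClassifier:
    """Wrap a Thumbs classifier with the NTSCG-criteria overlay.

    Every target category must be matched by some rule in the ruleset;
    unknown codes raise immediately rather than silently matching the
    fallback rating.
    """
    known = ruleset.matched_categories()
    unknown = sorted(set(target_categories) - known)
    if unknown:
        raise ValueError(f"target categories not matched by any NTSCG rule: {unknown}")
    return OverlayThumbsClassifier(
        inner=thumbs, ruleset=ruleset, target_categories=frozenset(target_categories)
    )


#: Categories the misalignment ranking flagged as the default overlay
#: targets: breakfast cereals, fruit/vegetable juices and drinks, and
#: pre-prepared meals (including pizza and savoury pasta/noodle dishes).
DEFAULT_OVERLAY_CATEGORIES: tuple[str, ...] = (
    "breakfast_cereal",
    "fruit_juice",
    "fruit_drink",
    "pre_prepared_meal",
    "pizza",
    "savoury_pasta_noodle",
)


@dataclasses.dataclass
class MisalignmentSourceReport:
    """Food groups ranked by added sugars sold among products healthy
    under Thumbs but not under NTSCG."""

    entries: list[tuple[str, float, float]]  # (category, added_sugars_sold, share of total %)
    n_misaligned: int

    def categories(self) -> list[str]:
        return [cat for cat, _, _ in self.entries]


def rank_misalignment_sources(
    linked: LinkedDataset,
    thumbs_tiers: Mapping[str, Tier],
    ntscg_tiers: Mapping[str, Tier],
    outcomes: pd.DataFrame,
) -> MisalignmentSourceReport:
    """Which categories drive added sugar into the Thumbs healthy tier.

    Selects products with Thumbs tier healthy and NTSCG tier below
    healthy, sums their added sugars sold per AHS minor group, and
    orders descending. Shares are of the grand added-sugars total.
    """
    by_id = linked.product_by_id
    grand = float(outcomes["added_sugars_sold"].sum())
    sums: dict[str, float] = {}
    n_mis = 0
    for pid, tier in thumbs_tiers.items():
        if tier is not Tier.HEALTHY or ntscg_tiers[pid] is Tier.HEALTHY:
            continue
        n_mis += 1
        cat = by_id[pid].ahs_minor_group
        sums[cat] = sums.get(cat, 0.0) + float(outcomes.at[pid, "added_sugars_sold"])
    entries = sorted(
        ((cat, s, 100.0 * s / grand if grand > 0 else 0.0) for cat, s in sums.items()),
        key=lambda e: (-e[1], e[0]),
    )
    return MisalignmentSourceReport(entries=entries, n_misaligned=n_mis)


@dataclasses.dataclass
class CoreFlagComparison:
    """Concordance of the two core/discretionary flag sources."""

    counts: dict[tuple[CoreStatus, CoreStatus], int]  # (source_db, abs) -> n
    n_discordant: int
    discordant_share: float  # percent of compared products
    discordant_ids: list[str]
    n_missing_abs: int = 0

    @property
    def n_compared(self) -> int:
        return sum(self.counts.values())


def apply_abs_core_flags(linked: LinkedDataset) -> tuple[LinkedDataset, CoreFlagComparison]:
    """Switch the governing core flags to the ABS classification.

    Returns the dataset (records carry both flag variants; downstream
    stages select ``core_source="abs"``) together with the 2x2
    concordance of the two flag sources. Products without an ABS flag
    are excluded from the comparison with a warning.
    """
    counts: dict[tuple[CoreStatus, CoreStatus], int] = {
        (a, b): 0 for a in CoreStatus for b in CoreStatus
    }
    discordant: list[str] = []
    missing: list[str] = []
    for p in linked.products:
        if p.core_abs is None or p.core_source_db is None:
            missing.append(p.product_id)
            continue
        counts[(p.core_source_db, p.core_abs)] += 1
        if p.core_source_db is not p.core_abs:
            discordant.append(p.product_id)
    if missing:
        warnings.warn(
            f"{len(missing)} products lack an ABS core flag and are excluded "
            f"from the flag comparison (e.g. {missing[:3]})"
        )
    n_compared = sum(counts.values())
    comparison = CoreFlagComparison(
        counts=counts,
        n_discordant=len(discordant),
        discordant_share=100.0 * len(discordant) / n_compared if n_compared else 0.0,
        discordant_ids=discordant,
        n_missing_abs=len(missing),
    )
    return linked, comparison


@dataclasses.dataclass
class ModificationReport:
    """Pre/post tier distributions of one modification (percent).

    ``pre``/``post``/``delta`` map layer -> tier -> value; a layer is
    ``None`` when its grand total is zero. ``direction_ok`` (overlay
    runs) is True iff no product moved to a healthier tier.
    """

    name: str
    pre: dict[str, Optional[dict[Tier, float]]]
    post: dict[str, Optional[dict[Tier, float]]]
    delta: dict[str, Optional[dict[Tier, float]]]
    n_reclassified: int
    direction_ok: Optional[bool] = None


def _distribution(
    tiers: Mapping[str, Tier], outcomes: pd.DataFrame
) -> dict[str, Optional[dict[Tier, float]]]:
    ids = list(tiers)
    sub = outcomes.reindex(ids)
    values = {
        "products": {pid: 1.0 for pid in ids},
        "discretionary_energy": dict(zip(ids, sub["discretionary_energy_sold"])),
        "added_sugars": dict(zip(ids, sub["added_sugars_sold"])),
    }
    out: dict[str, Optional[dict[Tier, float]]] = {}
    for layer in WEIGHT_LAYERS:
        totals = {t: 0.0 for t in TIER_DISPLAY}
        for pid, tier in tiers.items():
            totals[tier] += values[layer][pid]
        grand = sum(totals.values())
        out[layer] = {t: 100.0 * v / grand for t, v in totals.items()} if grand > 0 else None
    return out


def compare_pre_post(
    pre_tiers: Mapping[str, Tier],
    post_tiers: Mapping[str, Tier],
    outcomes: pd.DataFrame,
    name: str = "modification",
    check_direction: bool = False,
) -> ModificationReport:
    """Quantify a modification as post-minus-pre tier distributions."""
    if set(pre_tiers) != set(post_tiers):
        raise ValueError("pre and post tier assignments cover different product sets")
    pre = _distribution(pre_tiers, outcomes)
    post = _distribution(post_tiers, outcomes)
    delta: dict[str, Optional[dict[Tier, float]]] = {}
    for layer in WEIGHT_LAYERS:
        if pre[layer] is None or post[layer] is None:
            delta[layer] = None
        else:
            delta[layer] = {t: post[layer][t] - pre[layer][t] for t in TIER_DISPLAY}
    changed = [pid for pid in pre_tiers if pre_tiers[pid] is not post_tiers[pid]]
    direction_ok: Optional[bool] = None
    if check_direction:
        direction_ok = all(post_tiers[pid] < pre_tiers[pid] for pid in changed)
    return ModificationReport(
        name=name,
        pre=pre,
        post=post,
        delta=delta,
        n_reclassified=len(changed),
        direction_ok=direction_ok,
    )
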