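"""Cross-system alignment and performance statistics.

Given each system's tier assignment over the same retained product set
and the sales-weighted outcomes, this module cross-tabulates the share
of unique products, total discretionary energy sold and total added
sugars sold landing in each (tier, tier) cell; summarises extreme
disagreement (healthiest tier under one system, least-healthy under the
other); computes Cohen's chance-corrected agreement on the binary
healthy / not-healthy split; and ranks the systems by how much
discretionary energy and added sugar they capture in the unhealthy tier
versus how much leaks into the healthy tier.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifiers import Tier

__all__ = [
    "WEIGHT_LAYERS",
    "TIER_DISPLAY",
    "AlignmentMatrix",
    "AgreementResult",
    "SystemPerformance",
    "PerformanceReport",
    "crosstab",
    "extreme_disagreement",
    "cohens_kappa",
    "interpret_kappa",
    "performance",
]

#: The three weight bases of every cross-tab: unique product counts,
#: discretionary energy sold (kJ) and added sugars sold (g).
WEIGHT_LAYERS: tuple[str, ...] = ("products", "discretionary_energy", "added_sugars")

#: Row/column order of all 3x3 matrices, healthiest first.
TIER_DISPLAY: tuple[Tier, ...] = (Tier.HEALTHY, Tier.SOMEWHAT_HEALTHY, Tier.UNHEALTHY)

_TIER_POS = {t: i for i, t in enumerate(TIER_DISPLAY)}
_LAYER_COLUMN = {
    "discretionary_energy": "discretionary_energy_sold",
    "added_sugars": "added_sugars_sold",
}


@dataclasses.dataclass
class AlignmentMatrix:
    """3x3 cross-tabulation of two systems' tiers under three weight bases.

    ``weights[layer]`` holds absolute cell totals; ``pct[layer]`` holds
    the cell shares of the layer's grand total in percent, or ``None``
    when the grand total is zero (undefined, never NaN-propagated).
    Rows index the first system's tier, columns the second's, both in
    :data:`TIER_DISPLAY` order.
    """

    system_pair: tuple[str, str]
    n_products: int
    counts: np.ndarray
    weights: dict[str, np.ndarray]
    pct: dict[str, Optional[np.ndarray]]

    def layer_pct(self, layer: str) -> Optional[np.ndarray]:
        return self.pct[layer]

    def diagonal_pct(self, layer: str) -> Optional[float]:
        """Congruence: share landing in the same tier under both systems."""
        p = self.pct[layer]
        return None if p is None else float(np.trace(p))

    def to_frame(self, layer: str) -> pd.DataFrame:
        p = self.pct[layer]
        data = np.full((3, 3), np.nan) if p is None else p
        names = [t.name for t in TIER_DISPLAY]
        return pd.DataFrame(data, index=names, columns=names)


def _layer_totals(outcomes: pd.DataFrame, ids: Sequence[str]) -> dict[str, np.ndarray]:
    sub = outcomes.reindex(ids)
    return {
        "products": np.ones(len(ids)),
        "discretionary_energy": sub["discretionary_energy_sold"].to_numpy(dtype=float),
        "added_sugars": sub["added_sugars_sold"].to_numpy(dtype=float),
    }


def crosstab(
    tiers_a: Mapping[str, Tier],
    tiers_b: Mapping[str, Tier],
    outcomes: pd.DataFrame,
    system_pair: tuple[str, str] = ("A", "B"),
) -> AlignmentMatrix:
    """Weighted 3x3 cross-tab of two tier assignments.

    Both assignments must cover the identical product set; the outcomes
    frame (indexed by product id) supplies the weights.
    """
    if set(tiers_a) != set(tiers_b):
        raise ValueError("tier assignments cover different product sets")
    ids = sorted(tiers_a)
    missing = [pid for pid in ids if pid not in outcomes.index]
    if missing:
        raise ValueError(f"outcomes missing for products: {missing[:5]}")

    rows = np.array([_TIER_POS[tiers_a[pid]] for pid in ids], dtype=int)
    cols = np.array([_TIER_POS[tiers_b[pid]] for pid in ids], dtype=int)
    layer_values = _layer_totals(outcomes, ids)

    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    weights: dict[str, np.ndarray] = {}
    pct: dict[str, Optional[np.ndarray]] = {}
    for layer, values in layer_values.items():
        cells = np.zeros((3, 3))
        np.add.at(cells, (rows, cols), values)
        weights[layer] = cells
        total = cells.sum()
        pct[layer] = (100.0 * cells / total) if total > 0 else None
    return AlignmentMatrix(
        system_pair=system_pair, n_products=len(ids), counts=counts, weights=weights, pct=pct
    )


def extreme_disagreement(matrix: AlignmentMatrix) -> dict[str, Optional[float]]:
    """Share in the two corner cells — healthiest under one system,
    least healthy under the other — per weight layer (percent)."""
    i_h, i_u = _TIER_POS[Tier.HEALTHY], _TIER_POS[Tier.UNHEALTHY]
    out: dict[str, Optional[float]] = {}
    for layer in WEIGHT_LAYERS:
        p = matrix.pct[layer]
        out[layer] = None if p is None else float(p[i_h, i_u] + p[i_u, i_h])
    return out


def interpret_kappa(kappa: float) -> str:
    """Interpretive band for a kappa value (Landis–Koch style cut-offs)."""
    if kappa >= 1.0:
        return "perfect"
    bands = [
        (0.81, "near perfect"),
        (0.61, "substantial"),
        (0.41, "moderate"),
        (0.21, "fair"),
        (0.01, "slight"),
    ]
    for lo, name in bands:
        if kappa >= lo:
            return name
    return "poor"


@dataclasses.dataclass
class AgreementResult:
    """Chance-corrected agreement on a binary split.

    ``kappa`` is ``None`` in the degenerate case where both raters are
    constant and identical (expected agreement 1), with the reason in
    ``note``.
    """

    kappa: Optional[float]
    p_observed: float
    p_expected: float
    contingency: np.ndarray  # 2x2 counts: rows = rater A yes/no, cols = rater B yes/no
    band: Optional[str] = None
    note: Optional[str] = None


def cohens_kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> AgreementResult:
    """Cohen's kappa = (p_o - p_e) / (1 - p_e) on a binary labelling."""
    a = np.asarray(labels_a, dtype=bool)
    b = np.asarray(labels_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("labels must be equal-length, non-empty 1-d sequences")
    n = len(a)
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    p_o = (table[0, 0] + table[1, 1]) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row[0] * col[0] + row[1] * col[1])
    if np.array_equal(a, b):
        # identical labelings agree perfectly regardless of p_e
        if p_e >= 1.0 - 1e-15:
            return AgreementResult(
                kappa=None,
                p_observed=1.0,
                p_expected=1.0,
                contingency=table,
                note="degenerate: both raters constant and identical; kappa undefined",
            )
        return AgreementResult(
            kappa=1.0, p_observed=1.0, p_expected=p_e, contingency=table, band="perfect"
        )
    if p_e >= 1.0 - 1e-15:
        return AgreementResult(
            kappa=None,
            p_observed=float(p_o),
            p_expected=1.0,
            contingency=table,
            note="degenerate: expected agreement is 1; kappa undefined",
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        kappa=float(kappa),
        p_observed=float(p_o),
        p_expected=p_e,
        contingency=table,
        band=interpret_kappa(float(kappa)),
    )


@dataclasses.dataclass
class SystemPerformance:
    """Per-tier shares of each weight base for one system (percent).

    ``pct[layer][tier]``; a layer is ``None`` when its grand total is
    zero. ``healthy_energy_structural_zero`` marks the Thumbs-style
    case where the healthy tier cannot contain discretionary energy by
    construction (reported as not-applicable in formatted output).
    """

    system: str
    pct: dict[str, Optional[dict[Tier, float]]]
    healthy_energy_structural_zero: bool = False

    def capture(self, layer: str, tier: Tier) -> Optional[float]:
        layer_pct = self.pct[layer]
        return None if layer_pct is None else layer_pct[tier]


@dataclasses.dataclass
class PerformanceReport:
    systems: dict[str, SystemPerformance]
    best_performing: list[str]


def _tier_shares(
    tiers: Mapping[str, Tier], values: Mapping[str, float]
) -> Optional[dict[Tier, float]]:
    totals = {t: 0.0 for t in TIER_DISPLAY}
    for pid, tier in tiers.items():
        totals[tier] += values[pid]
    grand = sum(totals.values())
    if grand <= 0:
        return None
    return {t: 100.0 * v / grand for t, v in totals.items()}


def performance(
    tiers_by_system: Mapping[str, Mapping[str, Tier]],
    outcomes: pd.DataFrame,
    structural_zero_systems: frozenset[str] = frozenset({"thumbs"}),
) -> PerformanceReport:
    """Compare systems on unhealthy-tier capture and healthy-tier leakage.

    The best-performing system captures the highest share of
    discretionary energy and added sugars sold in its unhealthy tier
    and the lowest shares in its healthy tier. When no system wins all
    four criteria simultaneously, the systems winning the most criteria
    are reported (ties listed together).
    """
    systems: dict[str, SystemPerformance] = {}
    for name, tiers in tiers_by_system.items():
        ids = list(tiers)
        missing = [pid for pid in ids if pid not in outcomes.index]
        if missing:
            raise ValueError(f"outcomes missing for products: {missing[:5]}")
        sub = outcomes.reindex(ids)
        layers = {
            "products": {pid: 1.0 for pid in ids},
            "discretionary_energy": dict(zip(ids, sub["discretionary_energy_sold"])),
            "added_sugars": dict(zip(ids, sub["added_sugars_sold"])),
        }
        pct = {layer: _tier_shares(tiers, values) for layer, values in layers.items()}
        systems[name] = SystemPerformance(
            system=name,
            pct=pct,
            healthy_energy_structural_zero=name in structural_zero_systems,
        )

    # four ranking criteria: (layer, tier, direction) with +1 = higher is better
    criteria = [
        ("discretionary_energy", Tier.UNHEALTHY, +1),
        ("added_sugars", Tier.UNHEALTHY, +1),
        ("discretionary_energy", Tier.HEALTHY, -1),
        ("added_sugars", Tier.HEALTHY, -1),
    ]
    wins: dict[str, int] = {name: 0 for name in systems}
    for layer, tier, direction in criteria:
        scored = {
            name: perf.capture(layer, tier)
            for name, perf in systems.items()
            if perf.capture(layer, tier) is not None
        }
        if not scored:
            continue
        best = max(scored.values()) if direction > 0 else min(scored.values())
        for name, value in scored.items():
            if abs(value - best) < 1e-9:
                wins[name] += 1
    top = max(wins.values()) if wins else 0
    best_performing = sorted(name for name, w in wins.items() if w == top and top > 0)
    return PerformanceReport(systems=systems, best_performing=best_performing)
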