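"""Cross-tabulation, extreme disagreement, Cohen's kappa and performance."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foodtiers.alignment import (
    TIER_DISPLAY,
    WEIGHT_LAYERS,
    Tier,
    cohens_kappa,
    crosstab,
    extreme_disagreement,
    interpret_kappa,
    performance,
)


def _outcomes(weights: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """outcomes frame from {product_id: (disc_energy, added_sugars)}."""
    return pd.DataFrame(
        {
            "quantity_sold": 1,
            "discretionary_energy_sold": [v[0] for v in weights.values()],
            "added_sugars_sold": [v[1] for v in weights.values()],
        },
        index=pd.Index(list(weights), name="product_id"),
    )


def _kappa_bruteforce(n11: int, n10: int, n01: int, n00: int) -> Fraction:
    """Exact (p_o - p_e) / (1 - p_e) on the 2x2 table, in rationals."""
    n = n11 + n10 + n01 + n00
    p_o = Fraction(n11 + n00, n)
    p_e = Fraction(n11 + n10, n) * Fraction(n11 + n01, n) + Fraction(n01 + n00, n) * Fraction(
        n10 + n00, n
    )
    return (p_o - p_e) / (1 - p_e)


def _labels_from_table(n11, n10, n01, n00):
    a = [True] * (n11 + n10) + [False] * (n01 + n00)
    b = [True] * n11 + [False] * n10 + [True] * n01 + [False] * n00
    return a, b


class TestCohensKappa:
    def test_perfect_agreement(self):
        result = cohens_kappa([True, False, True], [True, False, True])
        assert result.kappa == 1.0
        assert result.band == "perfect"

    def test_hand_computed_moderate_table(self):
        # 20 both-healthy, 5 A-only, 10 B-only, 15 neither: p_o=0.7, p_e=0.5
        a, b = _labels_from_table(20, 5, 10, 15)
        result = cohens_kappa(a, b)
        assert result.p_observed == pytest.approx(0.7)
        assert result.p_expected == pytest.approx(0.5)
        assert result.kappa == pytest.approx(0.4)
        assert result.band == "fair"

    def test_complement_on_balanced_set_is_minus_one(self):
        a = [True, True, False, False]
        b = [not x for x in a]
        assert cohens_kappa(a, b).kappa == pytest.approx(-1.0)

    def test_degenerate_constant_identical_raters(self):
        result = cohens_kappa([True, True], [True, True])
        assert result.kappa is None
        assert "degenerate" in result.note

    def test_contingency_layout(self):
        result = cohens_kappa(*_labels_from_table(3, 2, 1, 4))
        assert result.contingency.tolist() == [[3, 2], [1, 4]]

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        n11=st.integers(0, 40),
        n10=st.integers(0, 40),
        n01=st.integers(0, 40),
        n00=st.integers(0, 40),
    )
    def test_matches_exact_bruteforce(self, n11, n10, n01, n00):
        if n11 + n10 + n01 + n00 == 0:
            return
        a, b = _labels_from_table(n11, n10, n01, n00)
        result = cohens_kappa(a, b)
        p_e = Fraction(n11 + n10, len(a)) * Fraction(n11 + n01, len(a)) + Fraction(
            n01 + n00, len(a)
        ) * Fraction(n10 + n00, len(a))
        if p_e == 1:
            assert result.kappa is None or result.kappa == 1.0
            return
        expected = _kappa_bruteforce(n11, n10, n01, n00)
        assert result.kappa == pytest.approx(float(expected), abs=1e-12)

    def test_agrees_with_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        a = rng.random(200) < 0.4
        b = rng.random(200) < 0.6
        ours = cohens_kappa(a, b).kappa
        theirs = sklearn_metrics.cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_interpretive_bands(self):
        assert interpret_kappa(0.5) == "moderate"
        assert interpret_kappa(0.7) == "substantial"
        assert interpret_kappa(0.9) == "near perfect"
        assert interpret_kappa(-0.2) == "poor"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cohens_kappa([], [])
        with pytest.raises(ValueError):
            cohens_kappa([True], [True, False])


class TestCrosstab:
    def test_identical_assignments_full_diagonal(self):
        tiers = {"a": Tier.HEALTHY, "b": Tier.SOMEWHAT_HEALTHY, "c": Tier.UNHEALTHY}
        outcomes = _outcomes({"a": (1.0, 2.0), "b": (3.0, 4.0), "c": (5.0, 6.0)})
        matrix = crosstab(tiers, dict(tiers), outcomes)
        for layer in WEIGHT_LAYERS:
            assert matrix.diagonal_pct(layer) == pytest.approx(100.0)

    def test_half_agreement_in_product_layer(self):
        tiers_a = {"a": Tier.HEALTHY, "b": Tier.HEALTHY}
        tiers_b = {"a": Tier.HEALTHY, "b": Tier.UNHEALTHY}
        matrix = crosstab(tiers_a, tiers_b, _outcomes({"a": (1, 1), "b": (1, 1)}))
        assert matrix.diagonal_pct("products") == pytest.approx(50.0)

    def test_hand_computed_weight_fractions(self):
        tiers_a = {"a": Tier.HEALTHY, "b": Tier.HEALTHY, "c": Tier.UNHEALTHY, "d": Tier.SOMEWHAT_HEALTHY}
        tiers_b = {"a": Tier.HEALTHY, "b": Tier.UNHEALTHY, "c": Tier.UNHEALTHY, "d": Tier.SOMEWHAT_HEALTHY}
        outcomes = _outcomes({"a": (10, 1), "b": (30, 2), "c": (40, 3), "d": (20, 4)})
        matrix = crosstab(tiers_a, tiers_b, outcomes)
        pct = matrix.pct["discretionary_energy"]
        # cell (HEALTHY, UNHEALTHY) holds product b: 30 of 100 kJ
        assert pct[0, 2] == pytest.approx(30.0)
        assert matrix.diagonal_pct("discretionary_energy") == pytest.approx(70.0)
        assert matrix.pct["added_sugars"][0, 2] == pytest.approx(20.0)

    def test_layers_sum_to_100(self, small_result):
        for matrix in small_result.matrices.values():
            for layer in WEIGHT_LAYERS:
                assert matrix.pct[layer].sum() == pytest.approx(100.0, abs=0.1)

    def test_zero_weight_layer_is_undefined_marker(self):
        tiers = {"a": Tier.HEALTHY}
        outcomes = _outcomes({"a": (0.0, 0.0)})
        matrix = crosstab(tiers, dict(tiers), outcomes)
        assert matrix.pct["discretionary_energy"] is None
        assert matrix.diagonal_pct("discretionary_energy") is None
        assert matrix.pct["products"] is not None

    def test_empty_product_set_is_undefined_not_nan(self):
        matrix = crosstab({}, {}, _outcomes({}))
        for layer in WEIGHT_LAYERS:
            assert matrix.pct[layer] is None

    def test_mismatched_product_sets_rejected(self):
        with pytest.raises(ValueError, match="different product sets"):
            crosstab({"a": Tier.HEALTHY}, {"b": Tier.HEALTHY}, _outcomes({"a": (1, 1)}))

    def test_permutation_invariance(self, small_result):
        tiers_a = small_result.tiers.thumbs
        tiers_b = small_result.tiers.ntscg
        shuffled_a = dict(reversed(list(tiers_a.items())))
        m1 = crosstab(tiers_a, tiers_b, small_result.outcomes)
        m2 = crosstab(shuffled_a, tiers_b, small_result.outcomes)
        for layer in WEIGHT_LAYERS:
            assert np.array_equal(m1.weights[layer], m2.weights[layer])


class TestExtremeDisagreement:
    def test_identical_assignments_zero(self):
        tiers = {"a": Tier.HEALTHY, "b": Tier.UNHEALTHY}
        matrix = crosstab(tiers, dict(tiers), _outcomes({"a": (1, 1), "b": (1, 1)}))
        assert extreme_disagreement(matrix)["products"] == pytest.approx(0.0)

    def test_one_in_ten_products(self):
        tiers_a = {f"p{i}": Tier.SOMEWHAT_HEALTHY for i in range(9)} | {"x": Tier.HEALTHY}
        tiers_b = {f"p{i}": Tier.SOMEWHAT_HEALTHY for i in range(9)} | {"x": Tier.UNHEALTHY}
        outcomes = _outcomes({pid: (1.0, 1.0) for pid in tiers_a})
        matrix = crosstab(tiers_a, tiers_b, outcomes)
        assert extreme_disagreement(matrix)["products"] == pytest.approx(10.0)

    def test_both_corners_counted(self):
        tiers_a = {"a": Tier.HEALTHY, "b": Tier.UNHEALTHY}
        tiers_b = {"a": Tier.UNHEALTHY, "b": Tier.HEALTHY}
        matrix = crosstab(tiers_a, tiers_b, _outcomes({"a": (1, 1), "b": (1, 1)}))
        assert extreme_disagreement(matrix)["products"] == pytest.approx(100.0)


class TestPerformance:
    def test_single_system_all_unhealthy(self):
        tiers = {"a": Tier.UNHEALTHY, "b": Tier.UNHEALTHY}
        outcomes = _outcomes({"a": (5, 1), "b": (5, 1)})
        report = performance({"sys": tiers}, outcomes)
        perf = report.systems["sys"]
        assert perf.capture("discretionary_energy", Tier.UNHEALTHY) == pytest.approx(100.0)
        assert perf.capture("added_sugars", Tier.UNHEALTHY) == pytest.approx(100.0)

    def test_hand_built_three_tier_fractions(self):
        tiers = {"a": Tier.HEALTHY, "b": Tier.SOMEWHAT_HEALTHY, "c": Tier.UNHEALTHY}
        outcomes = _outcomes({"a": (10, 5), "b": (30, 15), "c": (60, 80)})
        perf = performance({"sys": tiers}, outcomes).systems["sys"]
        assert perf.capture("discretionary_energy", Tier.UNHEALTHY) == pytest.approx(60.0)
        assert perf.capture("added_sugars", Tier.HEALTHY) == pytest.approx(5.0)
        assert perf.capture("products", Tier.SOMEWHAT_HEALTHY) == pytest.approx(100 / 3)

    def test_tier_shares_sum_to_100(self, small_result):
        for perf in small_result.performance.systems.values():
            for layer in WEIGHT_LAYERS:
                if perf.pct[layer] is not None:
                    assert sum(perf.pct[layer].values()) == pytest.approx(100.0, abs=0.1)

    def test_zero_total_layer_marked_undefined(self):
        tiers = {"a": Tier.HEALTHY}
        outcomes = _outcomes({"a": (0.0, 0.0)})
        perf = performance({"sys": tiers}, outcomes).systems["sys"]
        assert perf.pct["discretionary_energy"] is None

    def test_best_performing_dominant_system(self):
        tiers_good = {"a": Tier.UNHEALTHY, "b": Tier.HEALTHY}
        tiers_bad = {"a": Tier.HEALTHY, "b": Tier.UNHEALTHY}
        outcomes = _outcomes({"a": (100, 100), "b": (1, 1)})
        report = performance({"good": tiers_good, "bad": tiers_bad}, outcomes)
        assert report.best_performing == ["good"]

    def test_thumbs_marked_structurally_zero(self, small_result):
        perf = small_result.performance.systems["thumbs"]
        assert perf.healthy_energy_structural_zero
        assert perf.capture("discretionary_energy", Tier.HEALTHY) == 0.0
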