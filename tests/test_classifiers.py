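"""Thumbs, HSR-tier and NTSCG classifiers and the common tier mapping."""

from __future__ import annotations

import itertools

import pytest
import yaml

from conftest import make_product
from foodtiers.classifiers import (
    HSRTierBoundaries,
    MissingFieldError,
    NTSCGCondition,
    NTSCGRating,
    NTSCGRule,
    NTSCGRuleSet,
    ThumbsRating,
    ThumbsRuleTable,
    Tier,
    classify_hsr_tier,
    classify_ntscg,
    classify_thumbs,
    default_ntscg_ruleset,
    map_to_tier,
)
from foodtiers.records import HALF_STAR_GRID, CoreStatus


class TestTierMapping:
    @pytest.mark.parametrize(
        "rating, tier",
        [
            (ThumbsRating.DOUBLE_UP, Tier.HEALTHY),
            (ThumbsRating.UP, Tier.HEALTHY),
            (ThumbsRating.SIDEWAYS, Tier.SOMEWHAT_HEALTHY),
            (ThumbsRating.DOWN, Tier.UNHEALTHY),
            (NTSCGRating.GREEN, Tier.HEALTHY),
            (NTSCGRating.AMBER, Tier.SOMEWHAT_HEALTHY),
            (NTSCGRating.RED, Tier.UNHEALTHY),
            (Tier.HEALTHY, Tier.HEALTHY),
        ],
    )
    def test_surjection(self, rating, tier):
        assert map_to_tier(rating) is tier

    def test_tier_total_order(self):
        assert Tier.HEALTHY > Tier.SOMEWHAT_HEALTHY > Tier.UNHEALTHY


class TestHSRTiers:
    @pytest.mark.parametrize(
        "hsr, tier",
        [
            (3.5, Tier.HEALTHY),
            (5.0, Tier.HEALTHY),
            (2.5, Tier.SOMEWHAT_HEALTHY),
            (3.0, Tier.SOMEWHAT_HEALTHY),
            (2.0, Tier.UNHEALTHY),
            (0.5, Tier.UNHEALTHY),
        ],
    )
    def test_default_boundaries(self, hsr, tier):
        assert classify_hsr_tier(hsr) is tier

    def test_absent_hsr_instructs_exclusion(self):
        with pytest.raises(MissingFieldError, match="exclude"):
            classify_hsr_tier(None)

    def test_off_grid_value_rejected(self):
        with pytest.raises(ValueError, match="half-star"):
            classify_hsr_tier(3.25)

    def test_boundaries_must_leave_middle_tier(self):
        with pytest.raises(ValueError):
            HSRTierBoundaries(healthy_min=2.0, unhealthy_max=2.0)


class TestThumbs:
    def test_core_five_stars_is_double_up(self):
        p = make_product(core_source_db="core", hsr=5.0)
        assert classify_thumbs(p) is ThumbsRating.DOUBLE_UP

    def test_core_half_star_is_down(self):
        p = make_product(core_source_db="core", hsr=0.5)
        assert classify_thumbs(p) is ThumbsRating.DOWN

    @pytest.mark.parametrize("hsr", HALF_STAR_GRID)
    def test_discretionary_never_reaches_up_tiers(self, hsr):
        p = make_product(core_source_db="discretionary", hsr=hsr)
        assert classify_thumbs(p) in (ThumbsRating.SIDEWAYS, ThumbsRating.DOWN)

    @pytest.mark.parametrize(
        "status, hsr", list(itertools.product(list(CoreStatus), HALF_STAR_GRID))
    )
    def test_default_table_is_total_over_the_grid(self, status, hsr):
        assert isinstance(ThumbsRuleTable().rating_for(status, hsr), ThumbsRating)

    @pytest.mark.parametrize(
        "status, hsr", list(itertools.product(list(CoreStatus), HALF_STAR_GRID))
    )
    def test_no_extreme_disagreement_with_hsr_by_construction(self, status, hsr):
        thumbs_tier = map_to_tier(ThumbsRuleTable().rating_for(status, hsr))
        hsr_tier = classify_hsr_tier(hsr)
        assert not (thumbs_tier is Tier.HEALTHY and hsr_tier is Tier.UNHEALTHY)
        assert not (thumbs_tier is Tier.UNHEALTHY and hsr_tier is Tier.HEALTHY)

    def test_core_source_selection(self):
        p = make_product(core_source_db="core", core_abs="discretionary", hsr=4.0)
        assert classify_thumbs(p, core_source="source_db") is ThumbsRating.UP
        assert classify_thumbs(p, core_source="abs") is ThumbsRating.SIDEWAYS

    def test_missing_inputs_raise(self):
        with pytest.raises(MissingFieldError, match="hsr"):
            classify_thumbs(make_product(hsr=None))
        with pytest.raises(MissingFieldError, match="core flag"):
            classify_thumbs(make_product(core_source_db=None))

    def test_table_yaml_roundtrip(self, tmp_path):
        table = ThumbsRuleTable(double_up_min=4.0)
        path = tmp_path / "thumbs.yaml"
        table.to_yaml(path)
        assert ThumbsRuleTable.from_yaml(path) == table

    def test_invalid_band_order_rejected(self):
        with pytest.raises(ValueError):
            ThumbsRuleTable(up_min=2.0, core_down_max=3.0)


class TestNTSCG:
    def test_breakfast_cereal_sugar_override(self):
        cereal = make_product(ahs_minor_group="breakfast_cereal", total_sugars=25.0, added_sugars=20.0)
        assert classify_ntscg(cereal).rating is NTSCGRating.AMBER
        low = make_product(ahs_minor_group="breakfast_cereal", total_sugars=15.0, added_sugars=10.0)
        assert classify_ntscg(low).rating is NTSCGRating.GREEN

    def test_pizza_saturated_fat_at_threshold_is_amber(self):
        pizza = make_product(ahs_minor_group="pizza", saturated_fat=5.0)
        result = classify_ntscg(pizza)
        assert result.rating is NTSCGRating.AMBER
        assert result.rule_id == "pizza"

    def test_unmatched_category_gets_default(self):
        p = make_product(ahs_minor_group="mystery_group")
        result = classify_ntscg(p)
        assert result.rating is NTSCGRating.AMBER
        assert result.rule_id is None

    def test_explain_record_lists_every_condition(self):
        cereal = make_product(ahs_minor_group="breakfast_cereal", total_sugars=25.0, added_sugars=20.0)
        result = classify_ntscg(cereal)
        assert len(result.conditions_evaluated) == 2
        assert ("total_sugars per_100g gt 20.0", True) in result.conditions_evaluated

    def test_exempt_product_rejected(self):
        with pytest.raises(ValueError, match="exempt"):
            classify_ntscg(make_product(ntscg_exempt=True))

    def test_missing_serving_size_error_names_field_and_basis(self):
        pizza = make_product(
            ahs_minor_group="pizza", saturated_fat=1.0, serving_size=None, package_size=None
        )
        with pytest.raises(MissingFieldError, match="serving_size.*manufacturer_serve"):
            classify_ntscg(pizza)

    def test_juice_below_99_pct_is_red(self):
        juice = make_product(ahs_minor_group="fruit_juice", pct_fruit_veg_juice=60.0, serving_size=250.0, package_size=1000.0)
        assert classify_ntscg(juice).rating is NTSCGRating.RED

    def test_serving_basis_can_flip_a_rating(self):
        # passes the 300 g serve cap at the manufacturer serve, fails at package size
        juice = make_product(
            ahs_minor_group="fruit_juice",
            pct_fruit_veg_juice=100.0,
            serving_size=250.0,
            package_size=1000.0,
            net_weight=1000.0,
        )
        assert classify_ntscg(juice, serving_basis="manufacturer_serve").rating is NTSCGRating.AMBER
        assert classify_ntscg(juice, serving_basis="package_size").rating is NTSCGRating.RED

    def test_per_serve_nutrient_uses_serve_amount(self):
        # 1200 kJ/100 g x 250 g serve = 3000 kJ > 2500 kJ cap
        meal = make_product(
            ahs_minor_group="pre_prepared_meal",
            energy=1200.0,
            saturated_fat=1.0,
            serving_size=250.0,
            package_size=500.0,
            net_weight=500.0,
        )
        assert classify_ntscg(meal).rating is NTSCGRating.AMBER
        small_serve = make_product(
            ahs_minor_group="pre_prepared_meal",
            energy=1200.0,
            saturated_fat=1.0,
            serving_size=150.0,
            package_size=500.0,
            net_weight=500.0,
        )
        assert classify_ntscg(small_serve).rating is NTSCGRating.GREEN

    def test_flag_condition(self):
        fried = make_product(ahs_minor_group="snack_chips", deep_fried=True, energy=100.0, serving_size=30.0)
        assert classify_ntscg(fried).rating is NTSCGRating.RED

    def test_determinism_pure_function(self):
        p = make_product(ahs_minor_group="breakfast_cereal", total_sugars=25.0, added_sugars=10.0)
        ruleset = default_ntscg_ruleset()
        first = classify_ntscg(p, ruleset)
        for _ in range(3):
            again = classify_ntscg(p, ruleset)
            assert again.rating is first.rating
            assert again.conditions_evaluated == first.conditions_evaluated

    def test_first_matching_rule_wins(self):
        ruleset = NTSCGRuleSet(
            rules=[
                NTSCGRule(id="specific", match=["cat_a"], base="GREEN"),
                NTSCGRule(id="broad", match=["cat_a", "cat_b"], base="RED"),
            ]
        )
        assert classify_ntscg(make_product(ahs_minor_group="cat_a"), ruleset).rule_id == "specific"
        assert classify_ntscg(make_product(ahs_minor_group="cat_b"), ruleset).rule_id == "broad"

    def test_ruleset_yaml_roundtrip(self, tmp_path):
        ruleset = default_ntscg_ruleset()
        path = tmp_path / "rules.yaml"
        ruleset.to_yaml(path)
        assert NTSCGRuleSet.from_yaml(path) == ruleset

    def test_shipped_ruleset_flags_assumed_thresholds(self):
        ruleset = default_ntscg_ruleset()
        sources = {c.source for r in ruleset.rules for c in r.conditions}
        assert sources == {"guideline", "assumed"}

    def test_condition_validation(self):
        with pytest.raises(ValueError, match="unknown field"):
            NTSCGCondition(field="protein", op="gt", threshold=5)
        with pytest.raises(ValueError, match="non-negative"):
            NTSCGCondition(field="sodium", op="gt", threshold=-1)
        with pytest.raises(ValueError, match="if_met"):
            NTSCGRule(
                id="r", match=["x"], base="GREEN",
                conditions=[NTSCGCondition(field="sodium", op="gt", threshold=1)],
            )
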