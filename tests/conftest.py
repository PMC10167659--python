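from __future__ import annotations

import pytest

from foodtiers import (
    SimConfig,
    generate_catalog,
    generate_sales_frame,
    link_and_filter,
    main_analysis,
)
from foodtiers.records import ProductRecord


def make_product(**overrides) -> ProductRecord:
    """A fully populated, ratable product; override any field."""
    fields = dict(
        product_id="P1",
        description="test product",
        net_weight=375.0,
        serving_size=125.0,
        package_size=375.0,
        energy=180.0,
        saturated_fat=1.0,
        total_sugars=10.0,
        added_sugars=8.0,
        sodium=20.0,
        fibre=1.0,
        pct_fruit_veg_juice=0.0,
        artificially_sweetened=False,
        contains_confectionery=False,
        deep_fried=False,
        hsr=3.0,
        core_source_db="core",
        core_abs="core",
        ahs_minor_group="unmatched_group",
        source_db_category="unmatched_group",
        hsr_exempt=False,
        ntscg_exempt=False,
    )
    fields.update(overrides)
    return ProductRecord(**fields)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_products=400, n_stores=8, seed=123)


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return generate_catalog(small_config)


@pytest.fixture(scope="session")
def small_sales(small_catalog, small_config):
    return generate_sales_frame(small_catalog, small_config)


@pytest.fixture(scope="session")
def small_linked(small_catalog, small_sales):
    linked, report = link_and_filter(small_catalog, small_sales)
    return linked, report


@pytest.fixture(scope="session")
def small_result(small_linked):
    linked, _ = small_linked
    return main_analysis(linked)
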