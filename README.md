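# foodtiers

Validation tooling for rule-based packaged-food healthiness classification.

Remote-community store operators and nutrition researchers in Australia use
several competing systems to tell shoppers and canteens which packaged foods
are healthy: the **Thumbs rating** (double thumbs up / up / sideways / down,
derived from a product's Health Star Rating and its Australian Dietary
Guidelines core/discretionary status), the **Health Star Rating (HSR)** itself
(0.5–5 stars, collapsed here into three tiers with healthy ≥ 3.5 stars), and
the **Northern Territory School Canteen Guidelines (NTSCG)** traffic lights
(Green/Amber/Red, a predominantly food-category-based scheme with
category-specific nutrient, ingredient and serving-size criteria). None of
these is a gold standard, so their validity is assessed *convergently*: do
they put the same products — and, more importantly, the same sales-weighted
discretionary energy and added sugars — into the same healthiness tiers?

`foodtiers` implements that whole validation pipeline:

- a typed product/sales data model with delimited-text I/O and an auditable
  linkage/exclusion stage;
- the three classifiers, including a declarative, editable YAML rule engine
  for the NTSCG traffic lights and a configurable band table for Thumbs;
- sales-weighted outcomes: for each product, discretionary energy sold
  = net weight (g) × units sold × energy (kJ/100 g) / 100 (zero for core
  products) and added sugars sold = net weight × units × added sugars
  (g/100 g) / 100;
- alignment statistics: weighted 3×3 cross-tabulations, extreme-disagreement
  summaries, Cohen's κ = (p_o − p_e)/(1 − p_e) on the binary healthy split,
  and a best-performing-system ranking;
- modelled modifications: an NTSCG-criteria overlay on the Thumbs algorithm
  (demotion-only) and realignment of core/discretionary flags to the ABS
  classification, each quantified as pre/post tier distributions;
- sensitivity analyses: store-level decomposition, package-size serving
  basis, and re-admission of system-exempt sugar products;
- a seeded synthetic retail-data generator, because the real sales and
  composition data such studies use are proprietary. Its default preset
  emulates the analysed scale: 4000 products across 51 stores, roughly half
  discretionary, HSR negatively correlated with risk nutrients through a
  latent healthiness score.

## Worked example

```python
from foodtiers import (SimConfig, Tier, generate_catalog, generate_sales_frame,
                       link_and_filter, main_analysis)

config = SimConfig(n_products=1000, n_stores=10, seed=42)
catalog = generate_catalog(config)
sales = generate_sales_frame(catalog, config)
linked, report = link_and_filter(catalog, sales)
print(f"retained {report.n_retained} of {report.n_input} products; "
      f"excluded: {report.n_excluded_by_reason}")

result = main_analysis(linked)
kappa = result.kappa_thumbs_ntscg
print(f"kappa(thumbs, ntscg) = {kappa.kappa:.2f} ({kappa.band})")
for name, perf in result.performance.systems.items():
    print(f"{name:>6s}: unhealthy tier captures "
          f"{perf.capture('discretionary_energy', Tier.UNHEALTHY):.1f} % discretionary energy; "
          f"healthy tier leaks {perf.capture('discretionary_energy', Tier.HEALTHY):.1f} %")
```

prints

```
retained 959 of 1000 products; excluded: {'not_in_composition_db': 0, 'missing_added_sugar': 9, 'missing_ingredients': 3, 'missing_nutrition_panel': 11, 'system_exempt': 18}
kappa(thumbs, ntscg) = 0.51 (moderate)
thumbs: unhealthy tier captures 92.3 % discretionary energy; healthy tier leaks 0.0 %
   hsr: unhealthy tier captures 74.8 % discretionary energy; healthy tier leaks 7.7 %
 ntscg: unhealthy tier captures 72.4 % discretionary energy; healthy tier leaks 8.2 %
```

The exclusion report partitions every input product into retained or exactly
one exclusion reason. κ ≈ 0.5 is chance-corrected agreement between Thumbs
and NTSCG on the binary healthy split ("moderate" band). The Thumbs healthy
tier leaks exactly 0 % discretionary energy — a structural property: no
discretionary product can ever receive thumbs up or double thumbs up, and
only discretionary products carry discretionary energy.

The same pipeline is available from a shell:

```sh
foodtiers simulate --seed 42 --out-catalog catalog.csv --out-sales sales.csv
foodtiers classify --catalog catalog.csv --system all --explain
foodtiers align --catalog catalog.csv --sales sales.csv
foodtiers run --seed 42 --out report_dir/
```

`foodtiers align --kappa thumbs,hsr` refuses by default — Thumbs is derived
from the HSR, so the two are not independent raters (`--force` overrides).

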