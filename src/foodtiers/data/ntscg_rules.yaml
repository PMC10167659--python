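# NTSCG traffic-light ruleset over AHS-style minor food groups.
#
# First rule whose `match` list contains the product's category applies.
# Within a rule, if ANY condition is met the `if_met` rating overrides
# the `base` rating. Nutrient conditions evaluate per 100 g or per
# serve; `serving_size` conditions test the serve amount itself (grams;
# manufacturer serve by default, package size under the package basis).
#
# `source: guideline` marks thresholds taken from published guideline
# criteria; `source: assumed` marks editable placeholders standing in
# for the authoritative guideline tables, which are not reproduced here.
schema_version: 1
default_rating: AMBER
rules:
  - id: vegetables
    match: [vegetables]
    base: GREEN
  - id: fruit
    match: [fruit]
    base: GREEN
  - id: water
    match: [water]
    base: GREEN
    conditions:
      - {field: artificially_sweetened, op: eq, threshold: true, source: assumed}
    if_met: RED
  - id: breakfast_cereal
    match: [breakfast_cereal]
    base: GREEN
    conditions:
      # mixed grain fortified cereals: sugars > 20 g/100 g
      - {field: total_sugars, basis: per_100g, op: gt, threshold: 20, source: guideline}
      - {field: contains_confectionery, op: eq, threshold: true, source: assumed}
    if_met: AMBER
  - id: fruit_juice
    match: [fruit_juice]
    base: AMBER
    conditions:
      # fruit juices must be composed of at least 99 % juice
      - {field: pct_fruit_veg_juice, op: lt, threshold: 99, source: guideline}
      - {field: serving_size, op: gt, threshold: 300, source: assumed}
    if_met: RED
  - id: fruit_drink
    match: [fruit_drink]
    base: RED
  - id: soft_drink
    match: [soft_drink]
    base: RED
  - id: dairy_milk
    match: [dairy_milk]
    base: GREEN
    conditions:
      - {field: saturated_fat, basis: per_100g, op: gt, threshold: 2.4, source: assumed}
    if_met: AMBER
  - id: yoghurt
    match: [yoghurt]
    base: GREEN
    conditions:
      - {field: total_sugars, basis: per_100g, op: gt, threshold: 12, source: assumed}
      - {field: contains_confectionery, op: eq, threshold: true, source: assumed}
    if_met: AMBER
  - id: bread
    match: [bread]
    base: GREEN
    conditions:
      - {field: sodium, basis: per_100g, op: gt, threshold: 450, source: assumed}
    if_met: AMBER
  - id: pizza
    match: [pizza]
    base: GREEN
    conditions:
      # pizza: 5 g saturated fat per 100 g
      - {field: saturated_fat, basis: per_100g, op: ge, threshold: 5, source: guideline}
      - {field: energy, basis: per_serve, op: gt, threshold: 2500, source: assumed}
    if_met: AMBER
  - id: savoury_pasta_noodle
    match: [savoury_pasta_noodle]
    base: GREEN
    conditions:
      # savoury pasta/noodle and sauce dishes: 5 g saturated fat per 100 g
      - {field: saturated_fat, basis: per_100g, op: ge, threshold: 5, source: guideline}
      - {field: energy, basis: per_serve, op: gt, threshold: 2500, source: assumed}
    if_met: AMBER
  - id: pre_prepared_meal
    match: [pre_prepared_meal]
    base: GREEN
    conditions:
      - {field: saturated_fat, basis: per_100g, op: ge, threshold: 5, source: assumed}
      - {field: energy, basis: per_serve, op: gt, threshold: 2500, source: assumed}
      - {field: deep_fried, op: eq, threshold: true, source: assumed}
    if_met: AMBER
  - id: snack_chips
    match: [snack_chips]
    base: AMBER
    conditions:
      - {field: deep_fried, op: eq, threshold: true, source: assumed}
      - {field: energy, basis: per_serve, op: gt, threshold: 600, source: assumed}
    if_met: RED
  - id: biscuits
    match: [biscuits]
    base: RED
  - id: confectionery
    match: [confectionery, sugar]
    base: RED
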