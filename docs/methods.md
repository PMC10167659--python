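# Methods

## The three classification systems

**Thumbs.** A banded lookup on (core status, HSR). Defaults: core products
earn double thumbs up at ≥ 4.5 stars, thumbs up at ≥ 3.5, thumbs sideways
above 2.0 and thumbs down at ≤ 2.0; discretionary products are capped at
thumbs sideways (≥ 3.5 stars) and otherwise get thumbs down. The published
band table is not publicly reproduced, so these cut points are this
package's assumptions, chosen to satisfy every constraint the system is
documented to have: the healthy tier is exactly {double up, up}; no
discretionary product can reach it; discretionary energy can appear in the
sideways tier; and the bands can never extremely disagree with the HSR
tiers. All four band parameters are user-overridable (`ThumbsRuleTable`,
YAML-serialisable); the discretionary cap is a hard invariant, not a
default.

**HSR tiers.** healthy ≥ 3.5 stars (the conventional canteen-alignment
cut), unhealthy ≤ 2.0, somewhat healthy in between. The 2.0 cut is an
assumption (the somewhat/unhealthy boundary is not fixed by any public
source we encode); both cuts are configurable on the half-star grid and
must leave the middle tier non-empty.

**NTSCG.** A declarative rule engine over AHS-style minor food groups.
Each rule has a category matcher, a base traffic light, and optional
conditions (nutrient thresholds per 100 g or per serve, ingredient flags,
minimum juice content, serve-size caps) that switch the rule to an
override rating when any condition fires. First matching rule in file
order wins; unmatched categories get a configurable default (Amber).
The shipped `data/ntscg_rules.yaml` encodes the criteria the guidelines
are known to use; thresholds with published values (cereal sugars
> 20 g/100 g, pizza and savoury pasta/noodle dishes ≥ 5 g saturated
fat/100 g, ≥ 99 % juice for fruit juices) are tagged `source: guideline`,
every other number is tagged `source: assumed` and is an editable
placeholder — the engine and its semantics, not those numbers, are the
contract. Comparators are explicit per condition ("exceeds" wording maps
to `gt`, "with 5 g" to `ge`), never hard-coded. Every classification
returns an explain record (matched rule id, each condition's value
judgement) sufficient to justify the output.

All three systems map onto one ordered three-tier scale
(healthy > somewhat healthy > unhealthy): {double up, up} → healthy,
sideways → somewhat, down → unhealthy; Green/Amber/Red map positionally.

## Outcomes and their arithmetic

Per product: discretionary energy sold (kJ) = net weight (g) × units sold
× energy (kJ/100 g) / 100 for products whose governing core flag is
discretionary, exactly 0 for core products; added sugars sold (g) = net
weight × units × estimated added sugars (g/100 g) / 100 for all products.
Millilitres are treated as grams (density 1): package weight and volume
are used interchangeably in retail exports and no density data exist.

The per-product factor (net weight × panel value / 100) is computed once.
The default analysis sums integer per-store quantities per product
*before* multiplying by the factor, and the store-level mode applies the
same factor to per-store quantities. Pooling store-level results therefore
reproduces the aggregated analysis bit-for-bit — the only way to get an
exact decomposition under floating point. Classification does not depend
on the store, so store-level variation enters only through the weights.

## Linkage and exclusion

The input product set is the union of catalog rows and product codes in
the sales table. Each product is retained or excluded under exactly one
reason, the first that matches in a fixed order: not in the composition
database (sales code with no catalog row), missing added-sugar estimate,
missing ingredient-derived flags, missing nutrition-panel fields (energy,
saturated fat, total sugars, sodium, net weight — and serving size, which
per-serve NTSCG criteria need), and system-exempt (exempt category flags,
or no HSR / no core flag, i.e. not ratable by the systems at all). Each
reason can be disabled in config. Missing values are explicit absence
(`None`), never imputed zeros; classifiers declare their behaviour on
absence (they raise, naming the field and, for per-serve criteria, the
serving basis).

## Alignment and performance statistics

Cross-tabs are 3×3 over (tier_A, tier_B) with three weight layers: unique
products, discretionary energy sold, added sugars sold. Percentages are
of each layer's grand total; a zero-total layer is reported as an explicit
undefined marker, never NaN. Extreme disagreement sums the two corner
cells (healthy under one system, unhealthy under the other).

Cohen's κ = (p_o − p_e)/(1 − p_e) is computed from the 2×2 table on the
binary healthy / not-healthy split only (the 3×3 weighted variant is out
of scope), with the conventional interpretive bands (0.41–0.60 moderate,
etc.). The degenerate case p_e = 1 (both raters constant and identical)
is reported as undefined with an explanation. κ is not offered for Thumbs
vs HSR without `--force`: Thumbs is a function of the HSR, so the two are
not independent raters.

A system is best-performing when it captures the highest share of
discretionary energy and added sugars sold in its unhealthy tier and the
lowest shares in its healthy tier. When no system dominates all four
criteria, the systems winning the most criteria are reported together —
a documented tie-break, since a dominance winner need not exist.

## Modifications

**NTSCG overlay.** For a target category set (default: breakfast cereals,
fruit/vegetable juices and drinks, and pre-prepared meals including pizza
and savoury pasta/noodle dishes), a product whose NTSCG rating maps to a
lower tier than its Thumbs rating is demoted to the *worst* Thumbs rating
inside that lower tier (somewhat → sideways, unhealthy → down). The
overlay never promotes and is idempotent by construction. Replacing the
rating outright with the NTSCG-mapped tier would be the alternative
semantics; demotion-only was chosen because the modification's purpose is
to stop unhealthy products leaking upward, not to let a food-category
scheme overrule the HSR in the healthy direction. The demotion target is
configurable in code.

**ABS flag realignment.** The Thumbs classifier's governing core flag is
switched from the source-database assignment to the AHS/ABS one. Records
carry both flags, so the switch is a classifier parameter, not a data
rewrite; only discordant-flag products (canonically fruit drinks, which
the source database groups with juices and calls core) can change rating.
Products without an ABS flag are excluded from the concordance table with
a warning.

Both modifications are reported as pre/post tier distributions per weight
layer; deltas sum to zero per layer by construction and the overlay run
carries an explicit all-demotions direction check.

## Synthetic data generator

The generator emulates the structure the analyses assume, not any real
product list. Per product: a category is drawn from a 17-group mix
(vegetables through plain sugar); a discretionary flag from a per-category
probability; a single latent healthiness score z ~ Normal(±0.9, 1)
(positive shift for core products) then drives everything that must
correlate: HSR = clip(2.75 + 1.1·z + Normal(0, 0.35)) snapped to the
half-star grid, and each log-nutrient gets −0.25·z (fibre +0.2·z) added
to its category-specific location before log-normal noise. Added sugars
are a Beta-distributed share of total sugars (high for discretionary
products, near zero for fruit, vegetables, juice, milk and water), which
enforces added ≤ total by construction. Fruit drinks are generated core
under the source-database flag and discretionary under the ABS flag — the
discrepancy subset is exactly that category, and it is configurable.
Sales are zero-inflated log-normal (log-mean 3.0, log-sd 1.5, 5 % zeros),
floored to integer units per (product, store) — a heavy right tail, as
retail quantity data show. Small per-field missingness rates (0.3–1 %)
and a plain-sugar exempt category (2 % of the mix, plus a 0.2 % random
exempt rate) feed the exclusion stage.

The default preset is the study-scale condition: 4000 products, 51
stores, category mix and discretionary probabilities chosen so ~49 % of
products are discretionary. These values were fixed once as the
generator's defaults. Under them the systems agree in the informative
regime — κ(Thumbs, NTSCG) ≈ 0.5, product congruence 55–85 % depending on
the pair — rather than degenerately (κ near 0 or 1), which is what makes
the alignment analyses testable.

Randomness uses numpy's PCG64 (`default_rng`) seeded as
`[seed, stream]` with separate streams for catalog and sales; a fixed
seed reproduces datasets bit-for-bit across platforms.

What the generator does *not* emulate: real category taxonomies (AHS
codes are stand-in names), brand/description realism, sales correlation
across stores or seasons, products sold under multiple barcodes (treated
as distinct products), and the composition database's coverage gaps
(the not-in-database exclusion is exercised by tests, not by the
generator). Passing tests therefore demonstrate the pipeline's
correctness and its structural guarantees on any input with this shape —
not that any particular published percentage would be reproduced on the
proprietary data.

## Numerical choices

- Percentages are kept at full precision internally; presentation output
  rounds half-up to one decimal.
- Tier comparisons use the enum's total order (healthy > somewhat >
  unhealthy); rating ties never arise because every classifier is a total
  function of its inputs.
- κ is exact floating arithmetic on the 2×2 table; tests check it against
  an exact `Fraction` brute force to 1e-12 and against an independent
  library implementation.
- Zero-total weight layers, empty product sets and the degenerate κ case
  all return explicit undefined markers rather than NaN.
- Catalog round-trips write floats with `%.17g`, preserving full double
  precision.

## Known limitations

- The NTSCG `assumed` thresholds are placeholders; analyses of real data
  must replace them from the authoritative guideline tables before the
  traffic-light outputs mean anything nutritionally.
- The Thumbs band table and the HSR somewhat/unhealthy cut are
  assumptions, flagged and configurable, not asserted as the deployed
  systems' exact values.
- Sodium-driven misclassification (high-sodium, low-energy products) is
  outside the two outcome measures, as is any credit for beneficial
  components (fibre, wholegrain, fruit/vegetable content).
- Cohen's κ is reported as a point estimate without confidence intervals.
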