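# snacknrf

Nutrient-density profiling of children's snacks for nutrition researchers
and food-policy analysts: the Nutrient Rich Food index **NRF8.3** (and the
general NRFn.3 family), rule-based classification of back-of-pack
ingredient lists, WWEIA category statistics, and a calibrated synthetic
snack-dataset generator for end-to-end testing.

## The score

For a food with energy density *ED* (kcal/100 g), each nutrient amount is
first normalized to a 100-kcal basis. The score is

```
NRFn.3 = NRn − LIM

NRn  = Σ_{i=1..n} min(100 · content_i / DV_i, cap)      (per 100 kcal, cap = 100)
LIM  = Σ_{j=1..3} 100 · content_j / MRV_j               (per 100 kcal, uncapped)
```

The shipped default is NRF8.3: eight qualifying nutrients — protein
(DV 50 g), fiber (28 g), vitamin A (800 µg), vitamin C (80 mg), vitamin D
(15 µg), calcium (1 000 mg), iron (18 mg), potassium (4 700 mg) — and the
three nutrients to limit: added sugar (MRV 50 g), saturated fat (20 g),
sodium (2 400 mg). A total-sugar %MRV is reported alongside but never
enters LIM, since total sugars include those naturally present in fruit
and dairy. Any 1–15-nutrient qualifying set can be configured through a
YAML standards file (`src/snacknrf/data/standards_nrf8.3.yaml` is the
shipped default).

Ingredient labels are parsed in order of predominance and classified by
three rules: **dairy-first** (milk, yogurt, or cheese listed first; milk
powders/solids and milk chocolate never qualify, and neither does cream),
**fruit-first** (a whole fruit or puree first, or second after water;
never after sugar; concentrates, jams, pectins and flavors excluded), and
**FVN presence** (a fruit, vegetable, nut, peanut, or seed anywhere on
the list, with potato/corn chips excluded). Matching is driven by
editable plain-text lexicons under `src/snacknrf/data/lexicons/`.

## Worked example

```python
from snacknrf import ProductRecord, ReferenceStandards, score_product, classify_ingredients

std = ReferenceStandards()  # NRF8.3 defaults
p = ProductRecord(
    product_id="yog-001", name="strawberry yogurt", country="FR", wweia_code=1802,
    energy_per_100g=95.0,
    nutrients_per_100g={"protein": 3.4, "fiber": 0.2, "vitamin_a": 30.0,
                        "vitamin_c": 1.2, "vitamin_d": 1.0, "calcium": 120.0,
                        "iron": 0.1, "potassium": 150.0,
                        "saturated_fat": 1.8, "added_sugar": 8.0, "sodium": 45.0},
    total_sugar_per_100g=12.5,
    ingredient_text="whole milk (59.5%), sugar, strawberries (8%), milk proteins")

r = score_product(p, std)
print(r.energy_density, round(r.nr_subscore, 2), round(r.lim_subscore, 2),
      round(r.nrf_score, 2))
c = classify_ingredients(p.ingredient_text, p.wweia_code)
print(c.dairy_first, c.fruit_first, c.fvn_present)
```

prints

```
95.0 37.03 28.29 8.74
True False True
```

i.e. this yogurt delivers 37.03 summed %DV of qualifying nutrients per
100 kcal, 28.29 summed %MRV of nutrients to limit, hence NRF8.3 = 8.74;
its label is dairy-first (whole milk leads) and contains FVN (the
strawberries), but is not fruit-first.

The command line drives the same stages on product CSVs
(`snacknrf simulate|score|classify|summarize|compare|plot|run`):

```bash
snacknrf simulate --seed 1 --out products.csv
snacknrf run products.csv --out-dir out/
```

which writes the category summary table, both group-comparison tables
(fruit-or-dairy-first vs neither; FVN vs not), per-product scores and
flags, and four energy-density/NRF and LIM/NR scatterplots.

## Synthetic data

The 261-product multi-country snack sample the summary statistics
describe is proprietary marketing-research data, so the package ships a
seedable generator (`snacknrf.simulate`) reproducing its published
structure: 24 WWEIA categories with fixed counts and energy-density
targets, and ingredient-defined groups whose %DV/%MRV profiles per
100 kcal are calibrated to the published group means. Identical seeds
give byte-identical datasets; every generated label classifies exactly
to its intended flags. See `docs/methods.md` for the generation model
and its limits.

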