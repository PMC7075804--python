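# Methods

## Scoring model

The package implements the Nutrient Rich Food index NRFn.3 on a 100-kcal
basis. For a product with energy density ED (kcal/100 g) and per-100 g
content `content_i` of nutrient *i*:

- each qualifying nutrient's percent daily value per 100 kcal is
  `content_i / DV_i × 100 × 100 / ED`, truncated at the cap (100 by
  default) so no single fortified nutrient can dominate;
- each limiting nutrient's percent maximum recommended value is computed
  the same way against MRV_i and is **not** capped — all-sugar candy or
  a soft drink can legitimately exceed 100 %MRV;
- NRn is the sum of capped %DVs, LIM the sum of the three limiting
  %MRVs, and NRFn.3 = NRn − LIM, an exact identity maintained to the
  last bit.

A %MRV for total sugar (same 50 g reference as added sugar) is computed
and reported but excluded from LIM, because total sugars include those
occurring naturally in fruit and dairy.

Reference amounts ship as a YAML file; one US-based set is applied to
all four markets (US, CA, FR, UK) for cross-country uniformity. The
qualifying set is configurable from 1 to 15 nutrients; NRF8.3 (protein,
fiber, vitamins A/C/D, calcium, iron, potassium) is the default.
Beverages are treated per 100 g with 1 mL ≡ 1 g.

Numerical choices:

- **ED_MIN = 1 kcal/100 g.** The 100-kcal normalization divides by ED,
  so (near-)zero-energy products (plain water) raise an explicit
  unscorable-product error naming the product instead of returning
  infinities. Every real snack category sits at 40 kcal/100 g or more,
  so the threshold only excludes degenerate records.
- **Missing nutrients contribute 0** to the sub-scores, with a logged
  warning carrying the product id. This mirrors label data where a
  nutrient is absent from the panel; no imputation is attempted.
- Caps are applied per product before any aggregation; published-style
  tables round to 2 decimals at presentation time only.

## Ingredient-list rules

Labels are parsed into an ordered token tree: top-level commas separate
tokens, parentheses and square brackets nest sub-ingredients, and QUID
percentage declarations ("whole milk (59.5%)", "raspberry 5%") are
stored per token but play no role in classification — the rules use
order of predominance, not quantity. Serializing a tree and re-parsing
reproduces it exactly.

Classification is lexicon-driven (plain-text term files, one term per
line, `#` comments), with exclusion terms checked before inclusion
terms and matching on whole words within a token name, so "milk
chocolate" never matches "milk". The shipped English lexicons are the
package's own curation — the rules name exemplar terms (milk, yogurt,
cheese; whole fruits and purees; peanuts and seeds) but no exhaustive
vocabulary exists. Deliberate boundary decisions:

- **Cream is not dairy-first.** The rule enumerates milk, yogurt, and
  cheese; a cream-first ice cream therefore classifies as
  neither-first. This is the literal reading and is flagged here
  because reasonable curators could differ.
- Fruit concentrates, jams, pectins, and flavors never qualify, as
  fruit-first or as FVN (they act as sweeteners or aromas).
- Starchy vegetables: potato/corn tokens in chip-category products
  (WWEIA 5002/5004/5008) never earn FVN credit; the shipped vegetable
  lexicon conservatively omits potato and corn everywhere else too.
- Legumes other than peanuts are omitted from the default nut/seed
  lexicon; quinoa is treated as a grain, not a seed.
- Only the top-level name of the first token can satisfy the
  first-ingredient rules; sub-ingredients count for FVN presence only.
- Lexicons are English-only; non-English labels must be pre-translated
  or the lexicon files extended.

## Category statistics

Products map to 24 WWEIA snack categories by 4-digit code (shipped as a
CSV with disjoint code sets). Summaries report per-category n, mean and
sample SD (n−1 denominator; SD = 0 for singleton categories) of energy
density, LIM, and NRF8.3, plus an overall row whose n-weighted means
equal the pooled means exactly.

Group comparisons report, for each of 16 variables (eight %DVs, four
%MRVs including total sugar, ED, NR, LIM, NRF), the group means, SEMs
(SD/√n), and a plain two-group one-way ANOVA p-value (not Welch) — for
two groups F equals the square of the pooled-variance t statistic, an
identity the tests verify. No multiple-testing correction is applied
across rows; raw p-values are always stored, with <0.05 / <0.001 labels
added only in rendered tables. Groups with fewer than two members make
SEM and ANOVA undefined and raise an error from `compare_groups`; the
pipeline skips such a contrast with a warning.

## Synthetic-data generator

The benchmark snack survey (261 products, four countries) is
proprietary, so the generator emulates its published structure:

- **Category structure.** 24 categories with the published product
  counts and energy-density mean/SD targets. ED is drawn from a normal
  truncated below at ED_MIN whose location is solved (bracketing +
  Brent) so the *post-truncation* mean equals the target; without that
  correction, high-variance low-mean categories (whole fruit: mean 79,
  SD 71) would drift upward by ~20 kcal/100 g.
- **Ingredient flags.** Per-category Bernoulli probabilities for
  dairy-first, fruit-first (with a water-leading juice variant), and
  extra FVN presence, set so expected group sizes match the survey
  partition (≈115 fruit-or-dairy-first vs ≈146; ≈88 FVN vs ≈173).
  Category templates then build labels from term pools whose
  classification under the rule module equals the intended flags —
  exactly, for every product, a property the tests assert over the
  whole dataset.
- **Nutrient profiles.** Per-100 kcal %DV/%MRV amounts are drawn from
  zero-truncated normals conditioned on the joint (first-ingredient ×
  FVN) stratum. The four cell means are solved from the four published
  group margins: the two first-ingredient margins are reproduced
  exactly (a mean-preserving tilt within each margin), and the two FVN
  margins are fitted in least squares — the four margins slightly
  over-determine the 2×2 table, so they cannot all be exact. Cells
  pushed below a 0.05 % floor are clamped and their margin partner
  re-balanced. Per-product SDs are SEM × √n of the corresponding
  first-ingredient margin. Amounts convert to per-100 g through the
  drawn ED.
- **Sugars.** Total sugar = added sugar + an independent zero-truncated
  "natural" component, enforcing added ≤ total by construction while
  calibrating both published sugar rows in the mean. Note the published
  "neither" column prints added sugar %MRV (11.66) *above* total sugar
  %MRV (10.62) on the same 50 g reference — arithmetically impossible
  under added ≤ total — so the natural component is floored at
  0.5 %MRV and simulated total sugar in that stratum runs slightly
  above print. Its dispersion is set to its mean (CV = 1), a typical
  spread for a strictly positive composition component; the total-sugar
  SD is therefore emergent, not calibrated.
- **Determinism.** One `numpy.random.Generator` drives everything;
  identical seed and config give byte-identical datasets. A default
  seed ships so documentation examples are stable. Country assignment
  is uniform and cosmetic.

What the generator does **not** emulate: within-product correlations
between nutrients (draws are independent within a stratum, so NRF
variance within groups understates reality), per-category nutrient
signatures beyond the stratum means (a synthetic soda's LIM is drawn
from the neither-stratum profile, not a soda-specific one — published
per-category LIM/NRF summaries are therefore reproduced only in broad
pattern, while category ED and the group contrasts are calibrated),
brand names, serving sizes, or realistic label prose beyond what the
classifier consumes. Passing tests demonstrate that the pipeline
recovers the structure the generator encodes; they cannot validate the
rules against real proprietary labels.

Problem sizes used by the test suite: the study-scale dataset (261
products) for end-to-end checks; a ×100-scale dataset (26 100 products)
for calibration recovery, where each category's empirical ED mean must
land within 3 SE of target; a fixed 5-seed panel for the ±5-point check
on the ~30-point first-ingredient NRF gap, since a single study-scale
draw has a gap sampling SE of about 3 points; 1 000 random products for
the brute-force scoring oracle at 1e-9; and 10 000 permutations for the
ANOVA consistency check.

## Known limitations

- The ingredient lexicons are finite and English-only; recall on real
  labels depends on them.
- The FVN contrast is calibrated only in least squares given the exact
  first-ingredient margins; its simulated increment (~22 points)
  matches the published one closely but its group sizes vary by seed.
- Whether the benchmark applied the %DV cap before or after averaging
  is unknowable from the published tables; this package caps per
  product before aggregation.
- QUID percentages are parsed and preserved but unused by the rules,
  matching the order-based classification approach.
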