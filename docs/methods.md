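# Methods

This note records the models, constants and design choices behind the
package, in the order data flows through the pipeline.

## Questionnaire model

The packaged schema carries 43 items on the five-category weekly
frequency scale (variable codes c200–c211, c215–c220, c222–c246), the
fat-on-meat behaviour question (c221), the diet-drink preference (c247),
bread slices per day (c250), take-away frequency (c251), bread-type,
fat-type and milk-type tick questions, milk-use questions, slices spread
with fat (c275), and daily counts of caffeinated/decaffeinated tea,
coffee and cola plus sugar spoons per cup. Category labels are matched
case-insensitively after whitespace normalisation, with unicode dashes
mapped to hyphens and "per week"/"a week" treated as equivalent, so
transcription variants of the printed options compare equal. Missing is
an explicit `None`, never a coerced empty string. Raw storage coding is
standardised on labels (the original export coding is not public).

Two of the 43 weekly items — fried foods (c220) and, outside the weekly
block, take-away meals (c251) — have no food assignment in the portion
table and are treated as behaviour covariates: they are first-class
schema items but contribute nothing to nutrient totals. The published
drink-question block gives a code range, not per-code assignments;
the mapping used here (c300/c301 tea caffeinated/decaf, c302 tea sugar
spoons, c304/c305/c306 likewise for coffee, c310/c311 cola) is a package
convention.

## Portion assignments and composition

`data/portions_pregnancy.csv` transcribes the fixed food lists standing
in for one portion of each question, including the nutrient-specific
alternate lists (tagged `vitaminE`, `vitaminC`, `folate`, `retinol`,
`carotene`, `zinc`, `pyridoxine`, `niacin`, `fattyAcids`,
`totalFatEnergy`) and the fat-on-meat variants for the meat and poultry
questions (`fatAll`/`fatSome`/`fatNone`; "eats some" uses the printed
half-weight lean plus lean-and-fat rows, no interpolation). An
unanswered behaviour question falls back to the intermediate `fatSome`
split; "never eat meat" resolves to the lean list (those answers
normally co-occur with a zero meat frequency anyway). The roast-potato
question prints three alternative cooking fats with no selection rule;
the blended-oil food is the default and the lard/corn-oil rows are kept
under `altLard`/`altCornOil` tags that the resolver never selects. One
typographic food code in the tinned-juice block ("4-885") is normalised
to 1091, the code used for the same description elsewhere in the table.
Unmapped variant headers are a load error, not silently ignored.

The composition table gives nutrient densities per 100 g by food code,
in the column layout `food_code, description, <slot>_per100g...`. The
packaged table is **synthetic**: the 5th-edition McCance & Widdowson
database is licensed and is not redistributed, so each of the 222
referenced food codes receives densities from one of ~45 food-category
templates (plausible early-1990s UK magnitudes) with a deterministic
±15% per-(code, nutrient) jitter seeded from a CRC32 of the key. Lean
cuts are genuinely leaner than their lean-and-fat counterparts, liver is
retinol-rich, fortified breakfast cereals carry folate and iron, and so
on — enough structure for every downstream behaviour to be exercised,
with no claim that any single value is a database entry. Correctness of
the engine is defined against whatever table is supplied; a real table
in the same CSV format can be passed to `DerivationEngine` or
`ffqkit derive --composition`.

The tryptophan slot carries tryptophan/60 (its niacin-equivalent
contribution, the convention the published summary statistics follow:
niacin equivalents = niacin + trp/60), and `niacin_equiv_mg` is computed
as that sum.

## Frequency recoding and daily basics

The five categories recode to 0, 0.5, 2, 5.5 and 10 times/week; a
missing answer recodes to 0 ("rarely or never eaten"), which makes the
whole engine total on schema-valid input. Version-6 recodes: bread
slices bands <1 / 1–2 / 3–4 / ≥5 map to 0.5 / 1.5 / 3.5 / 5.5 slices/day
with missing → 1.5; slices spread with fat default to 2 when missing and
cap at 6 (banded answers such as "7–14 a day" parse to their midpoint
before the cap); soft drinks carry no frequency question, so the modal
2/week from a later questionnaire is imposed for everyone, scaled by the
diet-drink answer (Always → 0, Sometimes → 0.5, Not at all → 1; both
"don't drink soft drinks" and a missing answer scale to 0, following the
missing→never principle).

Type questions resolve to mixture shares: ticks weight 1 ("usually") or
0.5 ("sometimes") and renormalise; with nothing ticked the national
defaults apply (white bread, whole milk, soft margarine on bread,
blended vegetable oil for cooking). Dried milk and "other" milk have no
composition block; ticks on them are ignored and shares renormalise over
the six representable types. The fat-type portion lists sum to 100 g and
are used as per-gram mixtures. Cooking-fat shares are resolved and
recorded but add no intake term of their own — frying fat is already
embedded in the "fried in oil" food entries, so a separate term would
double-count.

Quantities the derivation needs but whose values were never published
are package defaults living in the overridable constants config: 7 g
spread per slice, 5 g sugar per spoon, per-use milk volumes (tea/coffee
30 ml, cereal/pudding 100 ml, drink/milky drink 200 ml). Milk uses enter
with their usually/sometimes weight, not multiplied by cup counts.

## Fish fatty acids and caffeine

n-3 per portion: white 0.32 g, oily 0.89 g, shellfish 0.35 g. The EPA
and DHA splits are **not** published ("calculated using the same
method"); the package defaults — white (0.06, 0.16), oily (0.26, 0.45),
shellfish (0.12, 0.13) g EPA/DHA per portion — were chosen so DHA
exceeds EPA at the population level (matching the published cohort means
of 0.07 vs 0.05 g/day) and EPA + DHA never exceeds total n-3; they are
config values labelled non-published. Caffeine: 7 × (caffeinated tea
cups × 27 + coffee cups × 57 + colas × 20) mg/week. Weekday/weekend
counts from earlier-gestation questionnaires collapse via
(5·weekday + 2·weekend)/7.

## Plausibility exclusions

The printed screen is a select-if chain: a record failing any rule is
removed from the whole nutrient output. The energy rule brackets the
**weekly** total in kJ (15,000–120,000, i.e. ≈2.1–17.1 MJ/day). The
remaining seventeen rules are read as **daily** upper caps (calcium
2,500 mg, carbohydrate 600 g, carotene 8,000 µg, cholesterol 1,000 mg,
folate 700 µg, iodine 450 µg, iron 40 mg, magnesium 700 mg, MUFA 70 g,
niacin equivalents 90 mg, NMES 350 g, phosphorus 3,500 mg, protein
200 g, retinol 8,000 µg, riboflavin 7 mg, selenium 350 µg, starch
400 g): every cap then sits 5–9 SD above the published daily means,
whereas a weekly reading would place several caps *below* the cohort
mean and exclude most of a realistic cohort, which is incompatible with
the published exclusion count. Comparisons are strict, matching the
select-if conditions. Only printed rules are applied; no bounds are
invented for unlisted nutrients. The fish fatty-acid stream was screened
separately in the source study but its rule was not published, so the
engine exposes a `fish_rules` hook and applies none by default.

## Dietary patterns

Patterns are principal components of the standardised (mean 0, SD 1,
population scaling) recoded frequency matrix — times/week, alcohol
excluded by construction since no alcohol item is in the matrix — with
the retained k components varimax-rotated (orthogonal rotation of the
orthonormal loading columns, so columns stay orthonormal and the
retained variance is preserved) and signed so each component's
largest-magnitude loading is positive. Scores are the standardised
projection `Z @ L`, giving training mean 0 per component; a participant
1 SD above the mean on a single item scores that item's loading row.
Scoring requires the complete item set — recoding upstream already
mapped missing answers to 0, so an absent column is an error, not a
silent zero. The item set entering the PCA is explicit (default: all 43
weekly items). Component names are manual metadata attached after
inspecting loadings, never assigned algorithmically.

## Energy standardisation and misreporter screening

Percent-energy uses conversion factors protein 17, fat 37, carbohydrate
16 kJ/g (config-stored); density mode divides any slot by energy in MJ.
The misreporter screen predicts the energy requirement as Schofield BMR
for women 18–29 y (0.062·kg + 2.036 MJ/day) × PAL 1.4 and classes the
reported/predicted ratio against Goldberg-style bounds 0.54–2.0; all
four constants are standard literature values in config, not taken from
the source publication. A missing pre-pregnancy weight yields
"plausible" with a logged caveat so the screen never silently drops
records.

## Synthetic cohorts

The generator draws k latent pattern scores per participant and sets the
true times/week of item j to `softplus(μ_j + Σ_k z_k·σ_k·Λ_kj + ε)`,
ε ~ N(0, 0.4²); the recorded answer is the five-category bin of that
value, with bin edges 0.25/1.25/3.5/7.5 chosen so category midpoints
track the recode weights. The default Λ plants five near-orthogonal
patterns mirroring the named patterns of the source cohort
(health-conscious, traditional, processed, confectionery, vegetarian
with negative red-meat/poultry loadings) at magnitudes 0.4–0.55 — strong
enough to be identifiable after binning, as the real cohort's patterns
were. Item means μ and the daily-basics distributions describe plausible
habits of pregnant women in early-1990s Britain and were calibrated once
so the default cohort's mean daily energy sits at the published scale
(≈7.2–7.3 MJ/day with SD ≈1 MJ); demographic proportions (education
35.3% A-level+, smoking 19.8%, housing 75.7% owned, ethnicity 97.4%
white, age 28.6 ± 4.8 y, BMI 22.9 ± 3.8) mirror the published FFQ-completer
table, with height N(1.63, 0.06²) m added so weight = BMI·height².

Injected under-reporting scales every continuous pre-categorisation
quantity (item frequencies, bread and spread slices, drink counts, sugar
spoons) by the misreport factor and steps milk-use levels down one notch
when the factor < 0.75, so "intake halved" halves derived energy rather
than only the weekly-item share. The factor is recorded in the latent
truth; the truth's `freq` is the post-factor, pre-binning value, so the
recorded category always bins the stored frequency.

What the generator does **not** emulate: real food-composition values,
within-person day-to-day variation, correlated item missingness,
digit-preference in counts, seasonal intake, or the published cohort's
exact means and SDs — passing recovery tests therefore demonstrates the
pipeline's internal correctness and statistical behaviour under known
truth, not agreement with the real cohort.

## Numerical choices

Weekly→daily conversion is exact division by 7; energy is additionally
reported in MJ (kJ/1000). The engine caches one nutrient-amount vector
per (question, behaviour) pair; the validation oracle
(`ffqkit.reference`) recomputes everything as an explicit
question × food × nutrient loop with its own recode table and no
caching, and the two agree to machine precision (the test bound is 1e-9
relative). Pattern fitting uses a full SVD, so results are deterministic
given the input; component sign is fixed by the largest-|loading| rule.
Degenerate inputs fail loudly: all-constant items cannot be
standardised, k cannot exceed the item count, exclusion rules must name
known slots with ordered bounds, and zero energy cannot be
standardised.

## Problem sizes

The test suite and the acceptance script run cohorts of 300–2,000
participants (10,000 for the demographic-proportion check), sizes at
which every recovery metric is stable across seeds while the whole suite
completes in well under a minute on one CPU.

## Known limitations

The packaged composition values are synthetic, so absolute nutrient
outputs are only of realistic magnitude, not reference values. The
alcohol-unit derivation, supplement-derived nutrients and the
biomarker-validation analyses of the source study are out of scope. The
fish-stream exclusion rule and the EPA/DHA per-portion constants are not
published; the package exposes the former as a hook and the latter as
labelled config defaults. Cooking-fat type contributes no direct intake
term (see above), and the weekday/weekend drink averaging is provided as
a helper rather than wired into the 32-week derivation, which uses the
32-week drink questions only.
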