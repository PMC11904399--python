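# ffqkit

Derivation of daily nutrient intakes, dietary-pattern scores and
plausibility screens from an **unquantified food frequency questionnaire
(FFQ)** of the kind administered to pregnant women at 32 weeks' gestation
in a large UK birth cohort: 43 food groups on a five-category weekly
frequency scale plus detailed questions on eight daily basics (bread,
milk, spreading and cooking fats, sugar in beverages, soft drinks,
tea/coffee/cola).

It is written for nutritional epidemiologists who need either (a) a
transparent, tested re-implementation of this classic derivation pipeline
to run against their own response and food-composition tables, or (b) a
synthetic-cohort laboratory for studying the pipeline's behaviour
(measurement error from category binning, misreporting screens, dietary
pattern recovery) when the real cohort data are access-controlled.

## The derivation

For participant *i* and nutrient *n*, the weekly intake is

```
W_in = Σ_q  f(a_iq) · Σ_{(food,g) ∈ P(q,n,b_i)}  (g / 100) · D(food, n)   +  basics_in
```

where `f` maps the five frequency categories to times/week
(0, 0.5, 2, 5.5, 10; an unanswered question counts as never eaten),
`P(q,n,b)` is the fixed food list standing in for one portion of question
*q* — possibly a nutrient-specific alternate list, or, for the meat and
poultry questions, a variant conditioned on the fat-on-meat behaviour
answer *b* — and `D` is the nutrient density per 100 g from a
food-composition table. `basics` adds bread (slices/day × 7 × per-slice
composition by bread-type share), spreading fat, total milk (summed daily
uses × per-use volume × milk-type densities), sugar in tea and coffee,
and soft drinks at a fixed 2/week scaled by the diet-drink answer.
Records outside printed plausibility bounds (weekly energy outside
15,000–120,000 kJ; per-nutrient daily caps) are removed whole, and weekly
totals are divided by 7.

Fish n-3/EPA/DHA and caffeine are closed forms over the seafood and drink
questions (n-3 per portion: white fish 0.32 g, oily 0.89 g, shellfish
0.35 g; caffeine 27 mg/cup tea, 57 mg/cup coffee, 20 mg/cola). Dietary
patterns are varimax-rotated principal components of the standardised
frequency matrix; AOAC fibre is NSP × 1.33; intakes can be standardised
as percent of energy or per MJ; misreporters are flagged by comparing
reported energy with a predicted requirement (Schofield BMR × physical
activity level, Goldberg-style ratio bounds).

Because the genuine food-composition database is licensed, the packaged
composition table is **synthetic** (plausible category-level densities
with deterministic per-food jitter); a real table in the same CSV format
drops in at runtime. See `docs/methods.md` for every modelling choice.

## Worked example

```python
import ffqkit as fk

resp = fk.FfqResponse("mum001", {
    "c202": "1-3 times a week",   # red meat
    "c221": "No",                 # cuts the fat off meat -> lean food codes
    "c205": "1-3 times a week",   # white fish
    "c206": "Once in 2 weeks",    # oily fish
    "c229": "4-7 times a week",   # fresh fruit
    "c238": "1-3 times a week",   # biscuits
    "c250": "3-4",                # bread slices per day
    "c252": True,                 # white bread
    "c276": "Yes usually",        # full-fat milk
    "c284": "Yes usually",        # milk in tea
    "c300": 3, "c302": 1,         # 3 caffeinated teas/day, 1 sugar each
    "c304": 1,                    # 1 caffeinated coffee/day
})
engine = fk.DerivationEngine()            # packaged portion + synthetic tables
weekly = engine.weekly_nutrients(resp)
kept, violated = fk.apply_exclusions(weekly, fk.load_exclusion_rules())
daily = fk.to_daily(weekly)
```

prints (with the packaged synthetic composition table):

```
kept: True  (violated rules: [])
energy        2.85 MJ/day
protein_g      27.46
fat_g          19.97
carbohydrate_g   91.63
nsp_g           3.37
n3_fish_g       0.15
caffeine_mg   138.00
protein       16.4 % of energy
```

Only six food questions were answered, and every unanswered question is
taken as "never or rarely eaten", so the energy total is low — exactly
the behaviour the missing-data rule prescribes.  The fish n-3 value is
(2 × 0.32 + 0.5 × 0.89)/7 = 0.155 g/day and caffeine is
7 × (3 × 27 + 57)/7 = 138 mg/day, independent of the composition table.
Feeding this energy to `fk.flag_misreporters(2.85, weight_kg=62.0)`
classes the record "under" (ratio 0.35 of the predicted 8.2 MJ/day
requirement) — the screen one would apply before analysis.

Whole cohorts go through `fk.derive_cohort(responses)`, and synthetic
cohorts with known latent diet structure come from
`fk.generate_cohort(fk.CohortConfig(n=2000), seed=1)`.

## Command line

```bash
ffqkit simulate --seed 3 --out cohort.csv            # + .truth/.demographics
ffqkit derive   --responses cohort.csv --out nutrients.csv
ffqkit patterns --responses cohort.csv --k 5 --out pat
ffqkit screen   --nutrients nutrients.csv --weights weights.csv --out flags.csv
```

`derive` writes a companion `*.exclusions.csv` naming the violated
plausibility rule(s) per removed participant.

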