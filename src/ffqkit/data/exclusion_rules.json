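{
  "comment": "Plausibility screen on derived intakes. SELECT-IF semantics: a record is kept only if every rule's condition holds; strict comparisons. The energy rule brackets the WEEKLY intake in kJ; all other rules are upper bounds on the DAILY value in the slot's unit.",
  "rules": [
    {"name": "energy", "slot": "energy_kj", "basis": "weekly", "lower": 15000, "upper": 120000},
    {"name": "calcium", "slot": "calcium_mg", "basis": "daily", "upper": 2500},
    {"name": "carbohydrate", "slot": "carbohydrate_g", "basis": "daily", "upper": 600},
    {"name": "carotene", "slot": "carotene_ug", "basis": "daily", "upper": 8000},
    {"name": "cholesterol", "slot": "cholesterol_mg", "basis": "daily", "upper": 1000},
    {"name": "folate", "slot": "folate_ug", "basis": "daily", "upper": 700},
    {"name": "iodine", "slot": "iodine_ug", "basis": "daily", "upper": 450},
    {"name": "iron", "slot": "iron_mg", "basis": "daily", "upper": 40},
    {"name": "magnesium", "slot": "magnesium_mg", "basis": "daily", "upper": 700},
    {"name": "mufa", "slot": "mufa_g", "basis": "daily", "upper": 70},
    {"name": "niacin_equiv", "slot": "niacin_equiv_mg", "basis": "daily", "upper": 90},
    {"name": "nmes", "slot": "nmes_g", "basis": "daily", "upper": 350},
    {"name": "phosphorus", "slot": "phosphorus_mg", "basis": "daily", "upper": 3500},
    {"name": "protein", "slot": "protein_g", "basis": "daily", "upper": 200},
    {"name": "retinol", "slot": "retinol_ug", "basis": "daily", "upper": 8000},
    {"name": "riboflavin", "slot": "riboflavin_mg", "basis": "daily", "upper": 7},
    {"name": "selenium", "slot": "selenium_ug", "basis": "daily", "upper": 350},
    {"name": "starch", "slot": "starch_g", "basis": "daily", "upper": 400}
  ]
}
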