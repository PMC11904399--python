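"""Straight-line reference implementation used for validation.

Re-derives one participant's weekly intakes as an explicit triple loop
(question x component food x nutrient) with its own frequency-weight
table, no caching and no vectorisation.  It shares only the loaded data
tables (portion assignments, composition, resolved daily basics) with the
production engine, so agreement between the two paths checks the engine's
summation, variant resolution and basics arithmetic rather than a single
shared code path.
"""

from __future__ import annotations

from .composition import CompositionTable, PortionTable
from .constants import DerivationConstants
from .derivation import resolve_basics
from .nutrients import COMPOSITION_SLOTS, NutrientVector
from .schema import FfqResponse, FfqSchema, normalise_label

_WEIGHTS = {
    "never or rarely": 0.0,
    "once in 2 weeks": 0.5,
    "1-3 times a week": 2.0,
    "4-7 times a week": 5.5,
    "more than once a day": 10.0,
}


def _freq(answer: str | None) -> float:
    if answer is None:
        return 0.0
    return _WEIGHTS[normalise_label(answer)]


def _portion_amount(
    portions: PortionTable,
    composition: CompositionTable,
    question: str,
    slot: str,
    behaviour: str | None,
) -> float:
    total = 0.0
    for code, grams in portions.portion_for(question, slot, behaviour):
        total += grams / 100.0 * composition.density(code, slot)
    return total


def brute_force_weekly(
    response: FfqResponse,
    portions: PortionTable,
    composition: CompositionTable,
    schema: FfqSchema,
    constants: DerivationConstants | None = None,
) -> NutrientVector:
    """Weekly nutrient vector by plain accumulation, slot by slot."""
    c = constants or DerivationConstants()
    basics = resolve_basics(response, c)
    behaviour = response.answers.get("c221")
    vec = NutrientVector(basis="weekly")

    for slot in COMPOSITION_SLOTS:
        total = 0.0
        for code in schema.derivable_weekly5_codes():
            f = _freq(response.answers.get(code))
            if f:
                total += f * _portion_amount(
                    portions, composition, schema[code].portion_question,
                    slot, behaviour)
        for pq, share in basics.bread_shares.items():
            total += (basics.bread_slices_per_day * 7.0 * share
                      * _portion_amount(portions, composition, pq, slot, None))
        for pq, share in basics.fat_spread_shares.items():
            total += (basics.spread_slices_per_day * 7.0
                      * c.spread_g_per_slice / 100.0 * share
                      * _portion_amount(portions, composition, pq, slot, None))
        ml = sum(w * c.milk_ml_per_use[use]
                 for use, w in basics.milk_use_factors.items())
        for pq, share in basics.milk_type_shares.items():
            total += (ml * 7.0 / 100.0 * share
                      * _portion_amount(portions, composition, pq, slot, None))
        grams_sugar = (basics.sugar_spoons_tea * basics.cups_tea
                       + basics.sugar_spoons_coffee * basics.cups_coffee
                       ) * c.sugar_g_per_spoon * 7.0
        total += grams_sugar / 100.0 * _portion_amount(
            portions, composition, "sugar", slot, None)
        total += (basics.soft_drinks_per_week * basics.sugary_drink_scale
                  * _portion_amount(portions, composition, "c4", slot, None))
        vec[slot] = total

    vec["niacin_equiv_mg"] = vec["niacin_mg"] + vec["tryptophan_mg"]
    fw, fo, fs = (_freq(response.answers.get(q)) for q in ("c205", "c206", "c207"))
    vec["n3_fish_g"] = (fw * c.fish.n3_per_portion["white"]
                        + fo * c.fish.n3_per_portion["oily"]
                        + fs * c.fish.n3_per_portion["shellfish"])
    vec["epa_fish_g"] = (fw * c.fish.epa_per_portion["white"]
                         + fo * c.fish.epa_per_portion["oily"]
                         + fs * c.fish.epa_per_portion["shellfish"])
    vec["dha_fish_g"] = (fw * c.fish.dha_per_portion["white"]
                         + fo * c.fish.dha_per_portion["oily"]
                         + fs * c.fish.dha_per_portion["shellfish"])
    vec["caffeine_mg"] = 7.0 * (
        basics.cups_tea_caff * c.caffeine.mg_per_cup_tea
        + basics.cups_coffee_caff * c.caffeine.mg_per_cup_coffee
        + basics.colas_caff * c.caffeine.mg_per_cola)
    return vec
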