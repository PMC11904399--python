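"""Core nutrient-derivation engine.

Weekly intake of each nutrient is the sum over FFQ questions of
``frequency(times/week) x nutrient content of one portion``, where the
portion's food list may be nutrient-specific or conditioned on the
fat-on-meat behaviour answer.  The eight daily basics (bread, spreading
fat, milk, sugar in beverages, soft drinks) are resolved from their own
questions and added on a per-day x 7 basis.  Unanswered frequency
questions are taken as "rarely or never eaten", so the engine is total on
any schema-valid response.  Weekly totals pass a plausibility screen and
are divided by seven to give daily intakes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema as sch
from .composition import (
    CompositionTable,
    PortionTable,
    packaged_portion_table,
    portion_nutrients,
    synthetic_composition,
)
from .constants import DerivationConstants
from .nutrients import (
    ALL_SLOTS,
    COMPOSITION_SLOTS,
    BasisError,
    NutrientVector,
)

log = logging.getLogger(__name__)

__all__ = [
    "DailyBasics",
    "ExclusionRule",
    "recode_frequency",
    "resolve_basics",
    "weekly_nutrients",
    "apply_exclusions",
    "to_daily",
    "load_exclusion_rules",
    "DerivationEngine",
    "derive_cohort",
]


def recode_frequency(
    category: str | None, constants: DerivationConstants | None = None
) -> float:
    """Map a five-category weekly answer to times per week.

    The published weights are 0, 0.5, 2, 5.5 and 10; an unanswered
    question maps to 0 (food assumed rarely or never eaten).
    """
    constants = constants or DerivationConstants()
    if category is None:
        return 0.0
    key = sch.normalise_label(category)
    for label, weight in constants.frequency_weights.items():
        if sch.normalise_label(label) == key:
            return weight
    raise ValueError(f"unknown frequency category: {category!r}")


@dataclass
class DailyBasics:
    """Resolved daily-basics quantities for one participant."""

    bread_slices_per_day: float
    spread_slices_per_day: float
    bread_shares: dict[str, float]       # portion question -> share
    milk_type_shares: dict[str, float]   # portion question -> share
    milk_use_factors: dict[str, float]   # use -> 0 / 0.5 / 1
    fat_spread_shares: dict[str, float]  # portion question -> share
    fat_cooking_shares: dict[str, float]
    sugar_spoons_tea: float
    sugar_spoons_coffee: float
    cups_tea: float        # caffeinated + decaffeinated, per day
    cups_coffee: float
    cups_tea_caff: float
    cups_coffee_caff: float
    colas_caff: float
    colas_decaf: float
    soft_drinks_per_week: float
    sugary_drink_scale: float


_USE_WEIGHT = {"Yes usually": 1.0, "Yes sometimes": 0.5, "No not at all": 0.0,
               None: 0.0}


def _shares(weights: dict[str, float], default_key: str) -> dict[str, float]:
    total = sum(weights.values())
    if total <= 0:
        return {default_key: 1.0}
    return {k: w / total for k, w in weights.items() if w > 0}


def _count(value, default: float = 0.0) -> float:
    if value is None:
        return default
    return max(float(value), 0.0)


def resolve_basics(
    response: sch.FfqResponse,
    constants: DerivationConstants | None = None,
) -> DailyBasics:
    """Resolve bread/milk/fat/sugar/soft-drink quantities for one response.

    Total by construction: missing answers recode to the published
    version-6 defaults (bread slices 1.5/day, spread slices 2/day capped
    at 6) or to the national-default type (white bread, whole milk, soft
    margarine on bread, blended vegetable oil for cooking).
    """
    c = constants or DerivationConstants()
    a = response.answers

    slices_cat = a.get("c250")
    if slices_cat is None:
        bread_slices = c.bread_slices_missing
    else:
        bread_slices = c.bread_slices_map[slices_cat]

    spread = a.get("c275")
    spread_slices = c.spread_slices_missing if spread is None else max(float(spread), 0.0)
    spread_slices = min(spread_slices, c.spread_slices_max)

    # bread types: yes/no ticks, equal weight; explicit "no bread" zeroes it
    if a.get(sch.BREAD_NONE_CODE) is True and not any(
        a.get(code) is True for code in sch.BREAD_TYPE_PORTION
    ):
        bread_shares: dict[str, float] = {}
        bread_slices = 0.0
    else:
        bread_shares = _shares(
            {pq: 1.0 for code, pq in sch.BREAD_TYPE_PORTION.items()
             if a.get(code) is True},
            default_key="c7a",
        )

    # milk types: usually 1, sometimes 0.5, renormalised over the types a
    # composition block exists for
    milk_weights = {}
    for code, pq in sch.MILK_TYPE_PORTION.items():
        if pq is None:
            continue
        w = _USE_WEIGHT.get(a.get(code), 0.0)
        if w > 0:
            milk_weights[pq] = milk_weights.get(pq, 0.0) + w
    milk_type_shares = _shares(milk_weights, default_key="c10a")

    milk_use_factors = {
        use: _USE_WEIGHT.get(a.get(code), 0.0)
        for use, code in sch.MILK_USE_CODES.items()
    }

    fat_q = {"a": None, "b": "c8b", "c": "c8c", "d": "c8d", "e": "c8e", "f": "c8f"}
    spread_w: dict[str, float] = {}
    cook_w: dict[str, float] = {}
    for letter, (bread_code, fry_code) in sch.FAT_TYPE_FLAGS.items():
        spread_q = "c8a_bread" if letter == "a" else fat_q[letter]
        cook_q = "c8a_cooking" if letter == "a" else fat_q[letter]
        if a.get(bread_code) is True:
            spread_w[spread_q] = spread_w.get(spread_q, 0.0) + 1.0
        if a.get(fry_code) is True:
            cook_w[cook_q] = cook_w.get(cook_q, 0.0) + 1.0
    fat_spread_shares = _shares(spread_w, default_key="c8b")
    fat_cooking_shares = _shares(cook_w, default_key="c8f")

    d = sch.DRINK_COUNT_CODES
    tea_caff = _count(a.get(d["tea_caff"]))
    tea_decaf = _count(a.get(d["tea_decaf"]))
    coffee_caff = _count(a.get(d["coffee_caff"]))
    coffee_decaf = _count(a.get(d["coffee_decaf"]))

    scale = 0.0
    diet = a.get("c247")
    if diet is not None:
        scale = c.diet_drink_scale[diet]

    return DailyBasics(
        bread_slices_per_day=bread_slices,
        spread_slices_per_day=spread_slices,
        bread_shares=bread_shares,
        milk_type_shares=milk_type_shares,
        milk_use_factors=milk_use_factors,
        fat_spread_shares=fat_spread_shares,
        fat_cooking_shares=fat_cooking_shares,
        sugar_spoons_tea=_count(a.get(d["sugar_tea"])),
        sugar_spoons_coffee=_count(a.get(d["sugar_coffee"])),
        cups_tea=tea_caff + tea_decaf,
        cups_coffee=coffee_caff + coffee_decaf,
        cups_tea_caff=tea_caff,
        cups_coffee_caff=coffee_caff,
        colas_caff=_count(a.get(d["cola_caff"])),
        colas_decaf=_count(a.get(d["cola_decaf"])),
        soft_drinks_per_week=c.soft_drink_per_week,
        sugary_drink_scale=scale,
    )


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

_N = len(COMPOSITION_SLOTS)
_SLOT_IX = {s: i for i, s in enumerate(COMPOSITION_SLOTS)}


class DerivationEngine:
    """Precomputes per-question portion nutrient vectors and derives
    weekly/daily intakes for whole cohorts."""

    def __init__(
        self,
        portions: PortionTable | None = None,
        composition: CompositionTable | None = None,
        constants: DerivationConstants | None = None,
        schema: sch.FfqSchema | None = None,
    ):
        self.portions = portions or packaged_portion_table()
        self.composition = composition if composition is not None else synthetic_composition(self.portions)
        self.constants = constants or DerivationConstants()
        self.schema = schema or sch.pregnancy_schema()
        self.portions.validate_defaults(
            [self.schema[c].portion_question
             for c in self.schema.derivable_weekly5_codes()]
        )
        self._cache: dict[tuple[str, str | None], np.ndarray] = {}

    # -- per-question portion amounts, variant-resolved per slot ------------
    def question_amounts(self, question_id: str, behaviour: str | None = None) -> np.ndarray:
        """Vector over composition slots of one portion's nutrient content,
        using each slot's variant food list where one exists."""
        key = (question_id, behaviour if self.portions.is_behaviour_question(question_id) else None)
        if key not in self._cache:
            vec = np.zeros(_N)
            for slot in COMPOSITION_SLOTS:
                comps = self.portions.portion_for(question_id, slot, behaviour)
                vec[_SLOT_IX[slot]] = sum(
                    g / 100.0 * self.composition.density(code, slot)
                    for code, g in comps
                )
            self._cache[key] = vec
        return self._cache[key]

    # -- weekly derivation ---------------------------------------------------
    def weekly_nutrients(self, response: sch.FfqResponse) -> NutrientVector:
        """Weekly intake vector for one participant (all 38 slots)."""
        c = self.constants
        basics = resolve_basics(response, c)
        behaviour = response.answers.get("c221")
        total = np.zeros(_N)

        # 43 weekly food-group questions (behaviour-only items contribute 0)
        for code in self.schema.derivable_weekly5_codes():
            freq = recode_frequency(response.answers.get(code), c)
            if freq == 0.0:
                continue
            pq = self.schema[code].portion_question
            total += freq * self.question_amounts(pq, behaviour)

        # bread: slices/day x 7 x per-slice composition by type share
        for pq, share in basics.bread_shares.items():
            total += (basics.bread_slices_per_day * 7.0 * share
                      * self.question_amounts(pq))

        # spreading fat: slices spread/day x 7 x g/slice x per-gram mixture
        for pq, share in basics.fat_spread_shares.items():
            total += (basics.spread_slices_per_day * 7.0
                      * c.spread_g_per_slice / 100.0 * share
                      * self.question_amounts(pq))

        # milk: summed daily uses x per-use volume x type-share densities x 7
        ml_per_day = sum(
            w * c.milk_ml_per_use[use]
            for use, w in basics.milk_use_factors.items()
        )
        for pq, share in basics.milk_type_shares.items():
            total += ml_per_day * 7.0 / 100.0 * share * self.question_amounts(pq)

        # sugar in tea and coffee: spoons x cups x 7 x per-spoon weight
        sugar_g = (basics.sugar_spoons_tea * basics.cups_tea
                   + basics.sugar_spoons_coffee * basics.cups_coffee
                   ) * c.sugar_g_per_spoon * 7.0
        total += sugar_g / 100.0 * self.question_amounts("sugar")

        # soft drinks: fixed 2/week, scaled by the diet-drink answer
        total += (basics.soft_drinks_per_week * basics.sugary_drink_scale
                  * self.question_amounts("c4"))

        vec = NutrientVector(
            values={s: float(total[_SLOT_IX[s]]) for s in COMPOSITION_SLOTS},
            basis="weekly",
        )
        vec["niacin_equiv_mg"] = vec["niacin_mg"] + vec["tryptophan_mg"]

        # fish fatty acids (closed form) and caffeine
        from .beverages import caffeine_weekly, fish_fatty_acids

        fw = recode_frequency(response.answers.get("c205"), c)
        fo = recode_frequency(response.answers.get("c206"), c)
        fs = recode_frequency(response.answers.get("c207"), c)
        n3_d, epa_d, dha_d = fish_fatty_acids(fw, fo, fs, c.fish)
        vec["n3_fish_g"] = n3_d * 7.0
        vec["epa_fish_g"] = epa_d * 7.0
        vec["dha_fish_g"] = dha_d * 7.0
        vec["caffeine_mg"] = caffeine_weekly(
            basics.cups_tea_caff, basics.cups_coffee_caff, basics.colas_caff,
            constants=c.caffeine,
        )
        return vec


def weekly_nutrients(
    response: sch.FfqResponse,
    portions: PortionTable | None = None,
    composition: CompositionTable | None = None,
    constants: DerivationConstants | None = None,
    schema: sch.FfqSchema | None = None,
) -> NutrientVector:
    """One-shot weekly derivation (builds a throwaway engine)."""
    return DerivationEngine(portions, composition, constants, schema).weekly_nutrients(response)


def frequency_matrix(
    responses: list[sch.FfqResponse],
    schema: sch.FfqSchema | None = None,
    constants: DerivationConstants | None = None,
    exclude_behaviour_only: bool = False,
) -> pd.DataFrame:
    """Recode a cohort's weekly5 answers to a participants x items
    times-per-week matrix (the dietary-pattern input)."""
    schema = schema or sch.pregnancy_schema()
    codes = (schema.derivable_weekly5_codes() if exclude_behaviour_only
             else schema.weekly5_codes())
    rows = [
        [recode_frequency(r.answers.get(c), constants) for c in codes]
        for r in responses
    ]
    return pd.DataFrame(
        rows, columns=codes,
        index=pd.Index([r.participant_id for r in responses],
                       name="participant_id"),
    )


# ---------------------------------------------------------------------------
# Plausibility exclusions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionRule:
    """One plausibility bound.  ``basis`` names the scale the printed bound
    refers to: the energy rule brackets the weekly kJ total, the remaining
    rules cap the daily value."""

    name: str
    slot: str
    basis: str = "daily"
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.slot not in ALL_SLOTS:
            raise ValueError(f"rule {self.name}: unknown nutrient slot {self.slot}")
        if self.basis not in ("weekly", "daily"):
            raise ValueError(f"rule {self.name}: bad basis {self.basis}")
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"rule {self.name}: lower bound must be below upper")

    def violations(self, weekly: NutrientVector) -> list[str]:
        v = weekly[self.slot]
        if self.basis == "daily":
            v = v / 7.0
        out = []
        if self.lower is not None and not v > self.lower:
            out.append(f"{self.name}_low")
        if self.upper is not None and not v < self.upper:
            out.append(f"{self.name}_high")
        return out


def load_exclusion_rules(path: str | Path | None = None) -> list[ExclusionRule]:
    """Load the packaged plausibility rules (or a JSON file of the same
    shape)."""
    if path is None:
        data = json.loads(
            (resources.files("ffqkit") / "data" / "exclusion_rules.json").read_text()
        )
    else:
        data = json.loads(Path(path).read_text())
    return [
        ExclusionRule(
            name=r["name"], slot=r["slot"], basis=r.get("basis", "daily"),
            lower=r.get("lower"), upper=r.get("upper"),
        )
        for r in data["rules"]
    ]


def apply_exclusions(
    vector: NutrientVector, rules: list[ExclusionRule]
) -> tuple[bool, list[str]]:
    """Screen a weekly vector; a record violating any rule is removed from
    the whole nutrient output (select-if chain semantics).

    Returns ``(kept, violated_rule_names)``.
    """
    if vector.basis != "weekly":
        raise BasisError("exclusion rules apply to weekly vectors")
    violated: list[str] = []
    for rule in rules:
        violated.extend(rule.violations(vector))
    return (len(violated) == 0, violated)


def to_daily(vector: NutrientVector) -> NutrientVector:
    """Divide every slot by seven; energy is additionally available in MJ
    via ``NutrientVector.energy_mj``."""
    return vector.to_daily()


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------


@dataclass
class CohortDerivation:
    """Result of deriving a whole cohort."""

    weekly: pd.DataFrame               # all participants, weekly basis
    daily: pd.DataFrame                # all participants, daily basis (+ energy_mj)
    exclusions: dict[str, list[str]]   # participant -> violated rule names
    fish_exclusions: dict[str, list[str]] = field(default_factory=dict)

    @property
    def kept(self) -> pd.DataFrame:
        return self.daily.loc[~self.daily.index.isin(self.exclusions)]


def derive_cohort(
    responses: list[sch.FfqResponse],
    portions: PortionTable | None = None,
    composition: CompositionTable | None = None,
    constants: DerivationConstants | None = None,
    schema: sch.FfqSchema | None = None,
    rules: list[ExclusionRule] | None = None,
    fish_rules: list[ExclusionRule] | None = None,
) -> CohortDerivation:
    """Run the full weekly-sum -> screen -> daily pipeline for a cohort.

    The main nutrient stream applies the packaged plausibility rules
    (whole-record removal); the fish fatty-acid stream is screened
    independently through ``fish_rules``, for which no published rule
    exists — the default applies none.
    """
    engine = DerivationEngine(portions, composition, constants, schema)
    if rules is None:
        rules = load_exclusion_rules()
    weekly_rows, daily_rows, ids = [], [], []
    exclusions: dict[str, list[str]] = {}
    fish_exclusions: dict[str, list[str]] = {}
    for resp in responses:
        wk = engine.weekly_nutrients(resp)
        kept, violated = apply_exclusions(wk, rules)
        if not kept:
            exclusions[resp.participant_id] = violated
        if fish_rules:
            fkept, fviol = apply_exclusions(wk, fish_rules)
            if not fkept:
                fish_exclusions[resp.participant_id] = fviol
        dy = wk.to_daily()
        ids.append(resp.participant_id)
        weekly_rows.append(dict(wk.values))
        daily_rows.append({**dy.values, "energy_mj": dy.energy_mj})
    weekly = pd.DataFrame(weekly_rows, index=pd.Index(ids, name="participant_id"))
    daily = pd.DataFrame(daily_rows, index=pd.Index(ids, name="participant_id"))
    return CohortDerivation(weekly=weekly, daily=daily, exclusions=exclusions,
                            fish_exclusions=fish_exclusions)
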