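"""Food-composition lookup and per-question portion assignments.

Each FFQ question maps to a fixed list of representative foods with gram
weights standing in for one consumption occasion (the "portion").  Some
questions carry alternate food lists used only when deriving particular
nutrients (e.g. a vitamin-E-specific list), and the meat/poultry questions
carry variants conditioned on the fat-on-meat behaviour answer.  Nutrient
densities come from a food-composition table keyed by food code, in the
format of the 5th-edition McCance & Widdowson database (per 100 g).

The packaged composition values are SYNTHETIC: the licensed database is not
bundled, so the package generates plausible densities per food code from
food-category templates with deterministic per-code jitter.  A real table
in the same CSV format can be supplied at runtime.
"""

from __future__ import annotations

import csv
import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrients import COMPOSITION_SLOTS

log = logging.getLogger(__name__)

__all__ = [
    "PortionAssignment",
    "PortionTable",
    "CompositionTable",
    "FishMix",
    "load_portion_table",
    "packaged_portion_table",
    "portion_nutrients",
    "synthetic_composition",
    "load_fish_mix",
    "NUTRIENT_VARIANT",
    "VARIANT_TAGS",
]

#: nutrient-specific variant tags, mapping composition slots to the tag of
#: the alternate food list used when deriving that nutrient.
NUTRIENT_VARIANT: dict[str, str] = {
    "vitamin_e_mg": "vitaminE",
    "vitamin_c_mg": "vitaminC",
    "folate_ug": "folate",
    "retinol_ug": "retinol",
    "carotene_ug": "carotene",
    "zinc_mg": "zinc",
    "vitamin_b6_mg": "pyridoxine",
    "niacin_mg": "niacin",
    "satfat_g": "fattyAcids",
    "mufa_g": "fattyAcids",
    "pufa_g": "fattyAcids",
    "fat_g": "totalFatEnergy",
    "energy_kj": "totalFatEnergy",
}

_BEHAVIOUR_TAGS = ("fatAll", "fatSome", "fatNone")
_ALT_TAGS = ("altLard", "altCornOil")  # printed roast-potato alternates, never auto-selected
VARIANT_TAGS = ("default", *sorted(set(NUTRIENT_VARIANT.values())),
                *_BEHAVIOUR_TAGS, *_ALT_TAGS)

#: fat-on-meat behaviour answer -> variant tag; unanswered behaviour falls
#: back to the intermediate "some of the fat" split.
BEHAVIOUR_VARIANT = {
    "Yes, all of it": "fatAll",
    "Yes, some of it": "fatSome",
    "No": "fatNone",
    "Never eat meat": "fatNone",
    None: "fatSome",
}


class PortionTableError(ValueError):
    pass


@dataclass(frozen=True)
class PortionAssignment:
    """One (question, variant) block: the foods composing one portion."""

    question_id: str
    variant: str
    components: tuple[tuple[str, float], ...]  # (food_code, grams)

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_TAGS:
            raise PortionTableError(
                f"{self.question_id}: unmapped variant tag {self.variant!r}"
            )
        for code, grams in self.components:
            if grams <= 0:
                raise PortionTableError(
                    f"{self.question_id}/{self.variant}: non-positive weight "
                    f"for food {code}"
                )

    @property
    def total_grams(self) -> float:
        return sum(g for _, g in self.components)


class PortionTable:
    """All portion assignments, with nutrient/behaviour variant resolution."""

    def __init__(self, assignments: list[PortionAssignment]):
        self._blocks: dict[tuple[str, str], PortionAssignment] = {}
        for a in assignments:
            key = (a.question_id, a.variant)
            if key in self._blocks:
                raise PortionTableError(f"duplicate (question, variant) block {key}")
            self._blocks[key] = a

    @property
    def assignments(self) -> list[PortionAssignment]:
        return list(self._blocks.values())

    def question_ids(self) -> list[str]:
        return sorted({q for q, _ in self._blocks})

    def has_question(self, question_id: str) -> bool:
        return any(q == question_id for q, _ in self._blocks)

    def is_behaviour_question(self, question_id: str) -> bool:
        return (question_id, "fatSome") in self._blocks

    def food_codes(self) -> list[str]:
        codes = {c for a in self._blocks.values() for c, _ in a.components}
        return sorted(codes)

    def portion_for(
        self,
        question_id: str,
        nutrient: str | None = None,
        behaviour: str | None = None,
    ) -> tuple[tuple[str, float], ...]:
        """Food components for one portion of ``question_id``.

        Returns the nutrient-specific list when one exists for ``nutrient``,
        otherwise the default; for the fat-on-meat questions the variant is
        selected from the ``behaviour`` answer instead.
        """
        if not self.has_question(question_id):
            raise PortionTableError(f"unknown question: {question_id}")
        if self.is_behaviour_question(question_id):
            tag = BEHAVIOUR_VARIANT.get(behaviour, "fatSome")
            return self._blocks[(question_id, tag)].components
        if nutrient is not None:
            tag = NUTRIENT_VARIANT.get(nutrient)
            if tag is not None and (question_id, tag) in self._blocks:
                return self._blocks[(question_id, tag)].components
        try:
            return self._blocks[(question_id, "default")].components
        except KeyError:
            raise PortionTableError(
                f"{question_id}: no default portion assignment"
            ) from None

    def validate_defaults(self, question_ids: list[str]) -> None:
        """Every listed question must resolve for every nutrient (fallback
        guarantee): a default block, or the full behaviour-variant set."""
        for q in question_ids:
            if not self.has_question(q):
                raise PortionTableError(f"portion table lacks question {q}")
            if self.is_behaviour_question(q):
                for tag in _BEHAVIOUR_TAGS:
                    if (q, tag) not in self._blocks:
                        raise PortionTableError(
                            f"{q}: incomplete fat-behaviour variants"
                        )
            elif (q, "default") not in self._blocks:
                raise PortionTableError(f"{q}: no default portion assignment")


def load_portion_table(path: str | Path) -> PortionTable:
    """Read a portion-assignment CSV (question_id, variant, food_code,
    description, grams)."""
    rows: dict[tuple[str, str], list[tuple[str, float]]] = {}
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"question_id", "variant", "food_code", "grams"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PortionTableError(
                f"portion table must have columns {sorted(required)}"
            )
        for rec in reader:
            q = rec["question_id"].strip()
            v = rec["variant"].strip()
            code = str(rec["food_code"]).strip()
            triple = (q, v, code)
            if triple in seen:
                raise PortionTableError(f"duplicate portion row {triple}")
            seen.add(triple)
            rows.setdefault((q, v), []).append((code, float(rec["grams"])))
    assignments = [
        PortionAssignment(q, v, tuple(comps)) for (q, v), comps in rows.items()
    ]
    return PortionTable(assignments)


def packaged_portion_table() -> PortionTable:
    """The packaged pregnancy-FFQ portion assignments."""
    with resources.as_file(
        resources.files("ffqkit") / "data" / "portions_pregnancy.csv"
    ) as p:
        return load_portion_table(p)


# ---------------------------------------------------------------------------
# Composition table
# ---------------------------------------------------------------------------


@dataclass
class CompositionTable:
    """Nutrient densities per 100 g by food code."""

    rows: dict[str, tuple[str, dict[str, float]]] = field(default_factory=dict)

    def add(self, code: str, description: str, densities: dict[str, float]) -> None:
        dens = {}
        for slot in COMPOSITION_SLOTS:
            v = float(densities.get(slot, 0.0))
            if v < 0:
                raise ValueError(f"{code}: negative density for {slot}")
            dens[slot] = v
        missing = [s for s in COMPOSITION_SLOTS if s not in densities]
        if missing:
            log.warning("food %s (%s): %d nutrient slots unresolved, set to 0",
                        code, description, len(missing))
        self.rows[str(code)] = (description, dens)

    def density(self, code: str, nutrient: str) -> float:
        try:
            return self.rows[str(code)][1][nutrient]
        except KeyError:
            raise KeyError(f"food code not in composition table: {code}") from None

    def __contains__(self, code: str) -> bool:
        return str(code) in self.rows

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for code, (desc, dens) in sorted(self.rows.items()):
            recs.append({"food_code": code, "description": desc,
                         **{f"{s}_per100g": dens[s] for s in COMPOSITION_SLOTS}})
        return pd.DataFrame(recs)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompositionTable":
        df = pd.read_csv(path, dtype={"food_code": str})
        table = cls()
        for _, row in df.iterrows():
            dens = {}
            for slot in COMPOSITION_SLOTS:
                col = f"{slot}_per100g"
                if col in df.columns and pd.notna(row[col]):
                    dens[slot] = float(row[col])
            table.add(row["food_code"], str(row.get("description", "")), dens)
        return table


def portion_nutrients(
    components: tuple[tuple[str, float], ...] | list[tuple[str, float]],
    table: CompositionTable,
) -> dict[str, float]:
    """Nutrient content of one portion: sum of grams/100 x density."""
    out = {slot: 0.0 for slot in COMPOSITION_SLOTS}
    for code, grams in components:
        if code not in table:
            raise KeyError(f"food code not in composition table: {code}")
        for slot in COMPOSITION_SLOTS:
            out[slot] += grams / 100.0 * table.density(code, slot)
    return out


# ---------------------------------------------------------------------------
# Fish mix (portion make-up behind the seafood fatty-acid estimates)
# ---------------------------------------------------------------------------


@dataclass
class FishMix:
    """Subtype make-up of one portion per fish class."""

    components: dict[str, tuple[tuple[str, float], ...]]

    def total_portion_grams(self, fish_class: str) -> float:
        return sum(g for _, g in self.components.get(fish_class, ()))


def load_fish_mix(path: str | Path | None = None) -> FishMix:
    if path is None:
        ctx = resources.as_file(resources.files("ffqkit") / "data" / "fish_mix.csv")
    else:
        ctx = None
    comps: dict[str, list[tuple[str, float]]] = {}

    def _read(p):
        with open(p, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                comps.setdefault(rec["fish_class"], []).append(
                    (rec["description"], float(rec["grams"]))
                )

    if ctx is not None:
        with ctx as p:
            _read(p)
    else:
        _read(path)
    return FishMix({k: tuple(v) for k, v in comps.items()})


# ---------------------------------------------------------------------------
# Synthetic composition generation
# ---------------------------------------------------------------------------

# Per-100 g density templates by food category.  Values are plausible
# 1990s-UK magnitudes, not database transcriptions; omitted slots are 0.
_T = {
    "processed_meat": dict(energy_kj=1150, protein_g=13, fat_g=22, satfat_g=8.5,
        mufa_g=9.5, pufa_g=2.5, cholesterol_mg=55, carbohydrate_g=10, starch_g=8,
        sugars_g=1, nmes_g=0.3, nsp_g=0.6, calcium_mg=60, potassium_mg=230,
        sodium_mg=900, phosphorus_mg=150, magnesium_mg=15, folate_ug=8,
        iron_mg=1.4, zinc_mg=1.8, thiamin_mg=0.2, riboflavin_mg=0.12,
        retinol_ug=5, vitamin_e_mg=0.35, vitamin_d_ug=0.6, vitamin_b6_mg=0.15,
        vitamin_b12_ug=1.0, niacin_mg=4.0, tryptophan_mg=2.6, carotene_ug=10,
        selenium_ug=7, iodine_ug=7),
    "red_meat": dict(energy_kj=1150, protein_g=26, fat_g=19, satfat_g=7.8,
        mufa_g=8.6, pufa_g=1.6, cholesterol_mg=85, potassium_mg=320,
        sodium_mg=320, phosphorus_mg=190, magnesium_mg=22, calcium_mg=10,
        folate_ug=10, iron_mg=2.3, zinc_mg=4.5, thiamin_mg=0.45,
        riboflavin_mg=0.2, retinol_ug=8, vitamin_e_mg=0.25, vitamin_d_ug=0.6,
        vitamin_b6_mg=0.3, vitamin_b12_ug=2.0, niacin_mg=6.5, tryptophan_mg=5.0,
        carotene_ug=5, selenium_ug=10, iodine_ug=8),
    "red_meat_lean": dict(energy_kj=800, protein_g=29, fat_g=9, satfat_g=3.5,
        mufa_g=3.9, pufa_g=0.9, cholesterol_mg=85, potassium_mg=360,
        sodium_mg=320, phosphorus_mg=210, magnesium_mg=25, calcium_mg=9,
        folate_ug=11, iron_mg=2.5, zinc_mg=5.0, thiamin_mg=0.5,
        riboflavin_mg=0.22, retinol_ug=5, vitamin_e_mg=0.15, vitamin_d_ug=0.5,
        vitamin_b6_mg=0.33, vitamin_b12_ug=2.2, niacin_mg=7.0, tryptophan_mg=5.6,
        carotene_ug=3, selenium_ug=11, iodine_ug=8),
    "poultry_skin": dict(energy_kj=900, protein_g=23, fat_g=14, satfat_g=3.9,
        mufa_g=6.1, pufa_g=2.9, cholesterol_mg=75, potassium_mg=280,
        sodium_mg=80, phosphorus_mg=190, magnesium_mg=22, calcium_mg=10,
        folate_ug=9, iron_mg=0.8, zinc_mg=1.4, thiamin_mg=0.07,
        riboflavin_mg=0.15, vitamin_e_mg=0.15, vitamin_d_ug=0.3,
        vitamin_b6_mg=0.3, vitamin_b12_ug=0.4, niacin_mg=7.5, tryptophan_mg=5.0,
        selenium_ug=8, iodine_ug=6),
    "poultry_lean": dict(energy_kj=620, protein_g=27, fat_g=5.5, satfat_g=1.6,
        mufa_g=2.4, pufa_g=1.2, cholesterol_mg=75, potassium_mg=310,
        sodium_mg=80, phosphorus_mg=210, magnesium_mg=24, calcium_mg=9,
        folate_ug=10, iron_mg=0.7, zinc_mg=1.5, thiamin_mg=0.08,
        riboflavin_mg=0.16, vitamin_e_mg=0.1, vitamin_d_ug=0.2,
        vitamin_b6_mg=0.35, vitamin_b12_ug=0.4, niacin_mg=8.5, tryptophan_mg=5.8,
        selenium_ug=9, iodine_ug=6),
    "offal": dict(energy_kj=700, protein_g=22, fat_g=8, satfat_g=2.6,
        mufa_g=2.1, pufa_g=1.6, cholesterol_mg=300, potassium_mg=250,
        sodium_mg=200, phosphorus_mg=300, magnesium_mg=20, calcium_mg=12,
        folate_ug=220, iron_mg=8.0, zinc_mg=4.0, vitamin_c_mg=10,
        thiamin_mg=0.3, riboflavin_mg=2.5, retinol_ug=6000, vitamin_e_mg=0.4,
        vitamin_d_ug=0.6, vitamin_b6_mg=0.5, vitamin_b12_ug=40,
        niacin_mg=10, tryptophan_mg=4.5, carotene_ug=30, selenium_ug=30,
        iodine_ug=10),
    "white_fish": dict(energy_kj=600, protein_g=16, fat_g=6, satfat_g=0.9,
        mufa_g=2.2, pufa_g=2.4, cholesterol_mg=40, carbohydrate_g=8,
        starch_g=7.5, sugars_g=0.3, nsp_g=0.3, calcium_mg=40, potassium_mg=300,
        sodium_mg=300, phosphorus_mg=180, magnesium_mg=22, folate_ug=12,
        iron_mg=0.5, zinc_mg=0.5, thiamin_mg=0.08, riboflavin_mg=0.08,
        vitamin_e_mg=0.6, vitamin_d_ug=1.5, vitamin_b6_mg=0.25,
        vitamin_b12_ug=1.5, niacin_mg=3.0, tryptophan_mg=3.5, selenium_ug=30,
        iodine_ug=80),
    "oily_fish": dict(energy_kj=850, protein_g=20, fat_g=13, satfat_g=2.8,
        mufa_g=5.0, pufa_g=3.8, cholesterol_mg=55, calcium_mg=80,
        potassium_mg=330, sodium_mg=400, phosphorus_mg=250, magnesium_mg=28,
        folate_ug=12, iron_mg=1.2, zinc_mg=0.9, thiamin_mg=0.1,
        riboflavin_mg=0.2, retinol_ug=45, vitamin_e_mg=1.5, vitamin_d_ug=8.0,
        vitamin_b6_mg=0.4, vitamin_b12_ug=8.0, niacin_mg=8.0, tryptophan_mg=4.3,
        selenium_ug=40, iodine_ug=45),
    "shellfish": dict(energy_kj=650, protein_g=15, fat_g=7, satfat_g=1.1,
        mufa_g=2.4, pufa_g=2.8, cholesterol_mg=90, carbohydrate_g=10,
        starch_g=9, sugars_g=0.3, nsp_g=0.4, calcium_mg=60, potassium_mg=240,
        sodium_mg=400, phosphorus_mg=200, magnesium_mg=35, folate_ug=18,
        iron_mg=1.5, zinc_mg=1.8, riboflavin_mg=0.08, vitamin_e_mg=0.8,
        vitamin_d_ug=0.2, vitamin_b6_mg=0.1, vitamin_b12_ug=6.0, niacin_mg=2.0,
        tryptophan_mg=3.0, selenium_ug=30, iodine_ug=50),
    "eggs": dict(energy_kj=700, protein_g=12.5, fat_g=12, satfat_g=3.4,
        mufa_g=4.8, pufa_g=1.7, cholesterol_mg=320, calcium_mg=60,
        potassium_mg=130, sodium_mg=160, phosphorus_mg=200, magnesium_mg=12,
        folate_ug=45, iron_mg=1.9, zinc_mg=1.3, riboflavin_mg=0.4,
        retinol_ug=160, vitamin_e_mg=1.1, vitamin_d_ug=1.6, vitamin_b6_mg=0.12,
        vitamin_b12_ug=2.2, niacin_mg=0.1, tryptophan_mg=3.0, selenium_ug=10,
        iodine_ug=45),
    "cheese": dict(energy_kj=1650, protein_g=25, fat_g=33, satfat_g=20.7,
        mufa_g=9.5, pufa_g=1.2, cholesterol_mg=95, sugars_g=0.1,
        calcium_mg=740, potassium_mg=90, sodium_mg=650, phosphorus_mg=500,
        magnesium_mg=27, folate_ug=30, iron_mg=0.3, zinc_mg=3.5,
        riboflavin_mg=0.45, retinol_ug=350, vitamin_e_mg=0.5, vitamin_d_ug=0.3,
        vitamin_b6_mg=0.1, vitamin_b12_ug=1.2, niacin_mg=0.1, tryptophan_mg=6.0,
        carotene_ug=200, selenium_ug=11, iodine_ug=40),
    "pizza": dict(energy_kj=1000, protein_g=9, fat_g=10, satfat_g=4.2,
        mufa_g=3.6, pufa_g=1.5, cholesterol_mg=15, carbohydrate_g=32,
        starch_g=26, sugars_g=4, nmes_g=1, nsp_g=2, calcium_mg=180,
        potassium_mg=170, sodium_mg=550, phosphorus_mg=160, magnesium_mg=20,
        folate_ug=25, iron_mg=1.0, zinc_mg=1.1, vitamin_c_mg=4,
        thiamin_mg=0.15, riboflavin_mg=0.12, retinol_ug=60, vitamin_e_mg=1.2,
        vitamin_d_ug=0.2, vitamin_b6_mg=0.1, vitamin_b12_ug=0.4, niacin_mg=1.5,
        tryptophan_mg=1.8, carotene_ug=300, selenium_ug=6, iodine_ug=12),
    "fried_potato": dict(energy_kj=900, protein_g=3.5, fat_g=9, satfat_g=1.8,
        mufa_g=3.8, pufa_g=3.0, carbohydrate_g=32, starch_g=30, sugars_g=1.5,
        nsp_g=2.5, calcium_mg=12, potassium_mg=650, sodium_mg=150,
        phosphorus_mg=70, magnesium_mg=25, folate_ug=25, iron_mg=0.8,
        zinc_mg=0.5, vitamin_c_mg=12, thiamin_mg=0.15, riboflavin_mg=0.02,
        vitamin_e_mg=1.2, vitamin_b6_mg=0.35, niacin_mg=1.2, tryptophan_mg=0.7,
        selenium_ug=2, iodine_ug=3),
    "crisps": dict(energy_kj=2200, protein_g=5.6, fat_g=34, satfat_g=14,
        mufa_g=13, pufa_g=6, carbohydrate_g=53, starch_g=47, sugars_g=0.7,
        nsp_g=5, calcium_mg=37, potassium_mg=1190, sodium_mg=1070,
        phosphorus_mg=130, magnesium_mg=56, folate_ug=35, iron_mg=1.8,
        zinc_mg=0.8, vitamin_c_mg=27, thiamin_mg=0.2, vitamin_e_mg=6.0,
        vitamin_b6_mg=0.8, niacin_mg=4.0, tryptophan_mg=1.1, selenium_ug=3,
        iodine_ug=4),
    "potato_plain": dict(energy_kj=320, protein_g=1.8, fat_g=0.1,
        carbohydrate_g=18, starch_g=17, sugars_g=0.7, nsp_g=1.4, calcium_mg=5,
        potassium_mg=360, sodium_mg=7, phosphorus_mg=37, magnesium_mg=15,
        folate_ug=20, iron_mg=0.4, zinc_mg=0.3, vitamin_c_mg=9,
        thiamin_mg=0.2, vitamin_b6_mg=0.3, niacin_mg=0.5, tryptophan_mg=0.4,
        selenium_ug=1, iodine_ug=2),
    "rice_pasta": dict(energy_kj=550, protein_g=3.5, fat_g=0.8, satfat_g=0.2,
        mufa_g=0.2, pufa_g=0.3, carbohydrate_g=30, starch_g=29.5, sugars_g=0.4,
        nsp_g=1.2, calcium_mg=10, potassium_mg=50, sodium_mg=2,
        phosphorus_mg=50, magnesium_mg=15, folate_ug=7, iron_mg=0.5,
        zinc_mg=0.6, thiamin_mg=0.02, vitamin_b6_mg=0.07, niacin_mg=1.2,
        tryptophan_mg=0.7, selenium_ug=4, iodine_ug=1),
    "legumes": dict(energy_kj=350, protein_g=5.5, fat_g=0.7, satfat_g=0.1,
        mufa_g=0.1, pufa_g=0.35, carbohydrate_g=13, starch_g=9, sugars_g=3.5,
        nmes_g=2, nsp_g=4.5, calcium_mg=45, potassium_mg=300, sodium_mg=400,
        phosphorus_mg=100, magnesium_mg=30, folate_ug=40, iron_mg=1.6,
        zinc_mg=0.9, vitamin_c_mg=1, thiamin_mg=0.08, riboflavin_mg=0.05,
        vitamin_e_mg=0.4, vitamin_b6_mg=0.12, niacin_mg=0.7, tryptophan_mg=1.1,
        carotene_ug=100, selenium_ug=2, iodine_ug=2),
    "curry": dict(energy_kj=600, protein_g=6, fat_g=6, satfat_g=0.8,
        mufa_g=2.2, pufa_g=2.5, carbohydrate_g=12, starch_g=8, sugars_g=2.5,
        nsp_g=4, calcium_mg=40, potassium_mg=350, sodium_mg=350,
        phosphorus_mg=110, magnesium_mg=35, folate_ug=35, iron_mg=2.0,
        zinc_mg=1.0, vitamin_c_mg=3, thiamin_mg=0.1, vitamin_e_mg=1.5,
        vitamin_b6_mg=0.15, niacin_mg=0.8, tryptophan_mg=1.2, carotene_ug=250,
        selenium_ug=3, iodine_ug=2),
    "vegetables": dict(energy_kj=110, protein_g=2.0, fat_g=0.4, pufa_g=0.2,
        carbohydrate_g=3.5, starch_g=0.7, sugars_g=2.5, nsp_g=2.4,
        calcium_mg=35, potassium_mg=230, sodium_mg=10, phosphorus_mg=50,
        magnesium_mg=12, folate_ug=60, iron_mg=0.8, zinc_mg=0.4,
        vitamin_c_mg=35, thiamin_mg=0.07, riboflavin_mg=0.05, vitamin_e_mg=0.7,
        vitamin_b6_mg=0.12, niacin_mg=0.4, tryptophan_mg=0.5, carotene_ug=700,
        selenium_ug=1, iodine_ug=2),
    "carrots": dict(energy_kj=100, protein_g=0.6, fat_g=0.3,
        carbohydrate_g=4.5, starch_g=0.2, sugars_g=4.2, nsp_g=2.5,
        calcium_mg=25, potassium_mg=120, sodium_mg=40, phosphorus_mg=15,
        magnesium_mg=5, folate_ug=12, iron_mg=0.4, zinc_mg=0.1,
        vitamin_c_mg=3, thiamin_mg=0.06, vitamin_e_mg=0.6, vitamin_b6_mg=0.08,
        niacin_mg=0.2, tryptophan_mg=0.1, carotene_ug=7500, selenium_ug=1,
        iodine_ug=2),
    "salad": dict(energy_kj=70, protein_g=0.9, fat_g=0.3, carbohydrate_g=2.5,
        sugars_g=2.3, nsp_g=1.1, calcium_mg=20, potassium_mg=220, sodium_mg=8,
        phosphorus_mg=25, magnesium_mg=8, folate_ug=30, iron_mg=0.5,
        zinc_mg=0.2, vitamin_c_mg=15, thiamin_mg=0.05, vitamin_e_mg=0.9,
        vitamin_b6_mg=0.1, niacin_mg=0.4, tryptophan_mg=0.2, carotene_ug=900,
        selenium_ug=1, iodine_ug=2),
    "fruit": dict(energy_kj=200, protein_g=0.5, fat_g=0.1, carbohydrate_g=11.5,
        starch_g=0.3, sugars_g=11.2, nsp_g=1.6, calcium_mg=15,
        potassium_mg=180, sodium_mg=3, phosphorus_mg=18, magnesium_mg=10,
        folate_ug=12, iron_mg=0.3, zinc_mg=0.1, vitamin_c_mg=25,
        thiamin_mg=0.04, vitamin_e_mg=0.3, vitamin_b6_mg=0.12, niacin_mg=0.3,
        tryptophan_mg=0.1, carotene_ug=60, selenium_ug=1, iodine_ug=1),
    "fruit_juice": dict(energy_kj=160, protein_g=0.5, fat_g=0.1,
        carbohydrate_g=9.5, sugars_g=9.3, nmes_g=9.3, calcium_mg=10,
        potassium_mg=130, sodium_mg=5, phosphorus_mg=13, magnesium_mg=9,
        folate_ug=15, iron_mg=0.3, zinc_mg=0.1, vitamin_c_mg=30,
        thiamin_mg=0.05, vitamin_b6_mg=0.06, niacin_mg=0.2, tryptophan_mg=0.1,
        carotene_ug=50, selenium_ug=1, iodine_ug=1),
    "pudding_cake": dict(energy_kj=1300, protein_g=4, fat_g=12, satfat_g=5.5,
        mufa_g=4.2, pufa_g=1.6, cholesterol_mg=55, carbohydrate_g=45,
        starch_g=22, sugars_g=23, nmes_g=20, nsp_g=1.2, calcium_mg=70,
        potassium_mg=130, sodium_mg=250, phosphorus_mg=90, magnesium_mg=14,
        folate_ug=10, iron_mg=1.0, zinc_mg=0.5, thiamin_mg=0.08,
        riboflavin_mg=0.08, retinol_ug=60, vitamin_e_mg=0.8, vitamin_d_ug=0.3,
        vitamin_b6_mg=0.05, vitamin_b12_ug=0.2, niacin_mg=0.6,
        tryptophan_mg=0.9, carotene_ug=60, selenium_ug=3, iodine_ug=10),
    "biscuits": dict(energy_kj=1950, protein_g=6, fat_g=21, satfat_g=10.5,
        mufa_g=7, pufa_g=2.5, cholesterol_mg=25, carbohydrate_g=65,
        starch_g=43, sugars_g=22, nmes_g=21, nsp_g=2, calcium_mg=90,
        potassium_mg=160, sodium_mg=400, phosphorus_mg=90, magnesium_mg=17,
        folate_ug=10, iron_mg=2.0, zinc_mg=0.6, thiamin_mg=0.15,
        riboflavin_mg=0.08, retinol_ug=25, vitamin_e_mg=1.5, vitamin_d_ug=0.3,
        vitamin_b6_mg=0.05, niacin_mg=1.3, tryptophan_mg=1.2, selenium_ug=3,
        iodine_ug=5),
    "crispbread": dict(energy_kj=1350, protein_g=9.5, fat_g=2.0, satfat_g=0.3,
        mufa_g=0.3, pufa_g=0.9, carbohydrate_g=70, starch_g=66, sugars_g=3,
        nsp_g=11.5, calcium_mg=45, potassium_mg=500, sodium_mg=220,
        phosphorus_mg=300, magnesium_mg=100, folate_ug=35, iron_mg=3.5,
        zinc_mg=3.0, thiamin_mg=0.28, riboflavin_mg=0.14, vitamin_e_mg=0.8,
        vitamin_b6_mg=0.29, niacin_mg=1.2, tryptophan_mg=1.8, selenium_ug=6,
        iodine_ug=3),
    "breakfast_cereal": dict(energy_kj=1450, protein_g=9, fat_g=3,
        satfat_g=0.7, mufa_g=1.0, pufa_g=1.1, carbohydrate_g=72, starch_g=52,
        sugars_g=18, nmes_g=14, nsp_g=9, calcium_mg=50, potassium_mg=400,
        sodium_mg=700, phosphorus_mg=250, magnesium_mg=80, folate_ug=250,
        iron_mg=12, zinc_mg=2.0, thiamin_mg=1.0, riboflavin_mg=1.3,
        vitamin_e_mg=0.6, vitamin_d_ug=2.8, vitamin_b6_mg=1.5,
        vitamin_b12_ug=1.7, niacin_mg=13, tryptophan_mg=2.0, selenium_ug=5,
        iodine_ug=4),
    "porridge": dict(energy_kj=210, protein_g=1.5, fat_g=1.1, satfat_g=0.2,
        mufa_g=0.4, pufa_g=0.4, carbohydrate_g=9, starch_g=8.7, sugars_g=0.3,
        nsp_g=0.8, calcium_mg=7, potassium_mg=45, sodium_mg=5,
        phosphorus_mg=45, magnesium_mg=26, folate_ug=7, iron_mg=0.5,
        zinc_mg=0.3, thiamin_mg=0.06, vitamin_e_mg=0.2, vitamin_b6_mg=0.03,
        niacin_mg=0.1, tryptophan_mg=0.4, selenium_ug=2, iodine_ug=1),
    "chocolate": dict(energy_kj=2200, protein_g=7.5, fat_g=30, satfat_g=17.7,
        mufa_g=9.7, pufa_g=1.1, cholesterol_mg=20, carbohydrate_g=57,
        starch_g=3, sugars_g=54, nmes_g=54, nsp_g=0.8, calcium_mg=220,
        potassium_mg=400, sodium_mg=120, phosphorus_mg=240, magnesium_mg=50,
        folate_ug=10, iron_mg=1.6, zinc_mg=1.1, riboflavin_mg=0.5,
        retinol_ug=40, vitamin_e_mg=0.7, vitamin_b12_ug=0.3, niacin_mg=0.4,
        tryptophan_mg=1.6, selenium_ug=3, iodine_ug=25),
    "chocolate_bar": dict(energy_kj=1850, protein_g=5, fat_g=17.5,
        satfat_g=8.5, mufa_g=6.5, pufa_g=1.0, cholesterol_mg=12,
        carbohydrate_g=67, starch_g=8, sugars_g=58, nmes_g=58, nsp_g=0.7,
        calcium_mg=160, potassium_mg=280, sodium_mg=150, phosphorus_mg=160,
        magnesium_mg=35, folate_ug=8, iron_mg=1.1, zinc_mg=0.8,
        riboflavin_mg=0.35, retinol_ug=25, vitamin_e_mg=0.6,
        vitamin_b12_ug=0.2, niacin_mg=0.3, tryptophan_mg=1.1, selenium_ug=2,
        iodine_ug=15),
    "sweets": dict(energy_kj=1450, protein_g=2, fat_g=5, satfat_g=3.0,
        mufa_g=1.5, pufa_g=0.3, carbohydrate_g=80, starch_g=4, sugars_g=75,
        nmes_g=75, calcium_mg=30, potassium_mg=60, sodium_mg=90,
        phosphorus_mg=25, magnesium_mg=8, iron_mg=0.8, zinc_mg=0.1,
        tryptophan_mg=0.3, selenium_ug=1, iodine_ug=2),
    "nuts": dict(energy_kj=2500, protein_g=18, fat_g=55, satfat_g=7,
        mufa_g=30, pufa_g=15, carbohydrate_g=7, starch_g=2, sugars_g=4,
        nsp_g=7, calcium_mg=80, potassium_mg=700, sodium_mg=200,
        phosphorus_mg=400, magnesium_mg=200, folate_ug=60, iron_mg=2.5,
        zinc_mg=3.2, thiamin_mg=0.5, riboflavin_mg=0.2, vitamin_e_mg=12,
        vitamin_b6_mg=0.5, niacin_mg=8, tryptophan_mg=3.0, selenium_ug=30,
        iodine_ug=3),
    "soy_products": dict(energy_kj=450, protein_g=9, fat_g=5.5, satfat_g=0.8,
        mufa_g=1.3, pufa_g=3.0, carbohydrate_g=3, starch_g=1.5, sugars_g=1,
        nsp_g=1.5, calcium_mg=350, potassium_mg=150, sodium_mg=250,
        phosphorus_mg=150, magnesium_mg=40, folate_ug=30, iron_mg=2.5,
        zinc_mg=1.2, thiamin_mg=0.1, riboflavin_mg=0.05, vitamin_e_mg=0.8,
        vitamin_b6_mg=0.1, niacin_mg=0.5, tryptophan_mg=1.9, carotene_ug=20,
        selenium_ug=3, iodine_ug=2),
    "tahini": dict(energy_kj=2500, protein_g=18.5, fat_g=58, satfat_g=8.3,
        mufa_g=21.7, pufa_g=25, carbohydrate_g=1, nsp_g=8, calcium_mg=680,
        potassium_mg=410, sodium_mg=20, phosphorus_mg=730, magnesium_mg=380,
        folate_ug=100, iron_mg=10.6, zinc_mg=5.4, thiamin_mg=0.9,
        riboflavin_mg=0.2, vitamin_e_mg=2.5, vitamin_b6_mg=0.15, niacin_mg=5,
        tryptophan_mg=3.8, selenium_ug=3, iodine_ug=2),
    "soft_drink": dict(energy_kj=180, carbohydrate_g=10.5, sugars_g=10.5,
        nmes_g=10.5, calcium_mg=4, potassium_mg=5, sodium_mg=8,
        phosphorus_mg=10, magnesium_mg=1, iodine_ug=1),
    "bread_white": dict(energy_kj=1000, protein_g=8.4, fat_g=1.9, satfat_g=0.4,
        mufa_g=0.4, pufa_g=0.7, carbohydrate_g=49, starch_g=46, sugars_g=2.6,
        nmes_g=0.5, nsp_g=1.5, calcium_mg=110, potassium_mg=110,
        sodium_mg=520, phosphorus_mg=90, magnesium_mg=24, folate_ug=30,
        iron_mg=1.6, zinc_mg=0.6, thiamin_mg=0.21, riboflavin_mg=0.06,
        vitamin_e_mg=0.1, vitamin_b6_mg=0.07, niacin_mg=1.7, tryptophan_mg=1.5,
        selenium_ug=5, iodine_ug=3),
    "bread_brown": dict(energy_kj=920, protein_g=8.5, fat_g=2.0, satfat_g=0.4,
        mufa_g=0.5, pufa_g=0.8, carbohydrate_g=44, starch_g=41, sugars_g=2.5,
        nsp_g=3.5, calcium_mg=100, potassium_mg=170, sodium_mg=540,
        phosphorus_mg=150, magnesium_mg=53, folate_ug=40, iron_mg=2.2,
        zinc_mg=1.0, thiamin_mg=0.24, riboflavin_mg=0.09, vitamin_e_mg=0.2,
        vitamin_b6_mg=0.1, niacin_mg=2.5, tryptophan_mg=1.6, selenium_ug=8,
        iodine_ug=3),
    "bread_wholemeal": dict(energy_kj=920, protein_g=9.2, fat_g=2.5,
        satfat_g=0.5, mufa_g=0.6, pufa_g=1.0, carbohydrate_g=42, starch_g=39,
        sugars_g=2.6, nsp_g=5.8, calcium_mg=54, potassium_mg=230,
        sodium_mg=550, phosphorus_mg=200, magnesium_mg=76, folate_ug=40,
        iron_mg=2.7, zinc_mg=1.8, thiamin_mg=0.26, riboflavin_mg=0.09,
        vitamin_e_mg=0.3, vitamin_b6_mg=0.12, niacin_mg=4.1, tryptophan_mg=1.9,
        selenium_ug=35, iodine_ug=3),
    "bread_flat": dict(energy_kj=1200, protein_g=8, fat_g=5, satfat_g=1.2,
        mufa_g=1.8, pufa_g=1.5, carbohydrate_g=48, starch_g=45, sugars_g=3,
        nsp_g=3, calcium_mg=90, potassium_mg=160, sodium_mg=400,
        phosphorus_mg=120, magnesium_mg=40, folate_ug=25, iron_mg=2.0,
        zinc_mg=1.0, thiamin_mg=0.2, riboflavin_mg=0.07, vitamin_e_mg=0.5,
        vitamin_b6_mg=0.1, niacin_mg=2.5, tryptophan_mg=1.5, selenium_ug=10,
        iodine_ug=3),
    "butter": dict(energy_kj=3000, protein_g=0.5, fat_g=82, satfat_g=52,
        mufa_g=21, pufa_g=3, cholesterol_mg=180, calcium_mg=15,
        potassium_mg=15, sodium_mg=750, phosphorus_mg=24, magnesium_mg=2,
        retinol_ug=815, vitamin_e_mg=2.0, vitamin_d_ug=0.8, carotene_ug=430,
        iodine_ug=38),
    "animal_fat": dict(energy_kj=3300, fat_g=99, satfat_g=42, mufa_g=40,
        pufa_g=10, cholesterol_mg=90, sodium_mg=5, vitamin_e_mg=1.0,
        vitamin_d_ug=1.0, retinol_ug=30, carotene_ug=20),
    "margarine": dict(energy_kj=3000, protein_g=0.2, fat_g=81, satfat_g=26,
        mufa_g=30, pufa_g=20, cholesterol_mg=7, sodium_mg=800, calcium_mg=4,
        retinol_ug=800, vitamin_e_mg=8.0, vitamin_d_ug=7.9, carotene_ug=300),
    "pufa_spread": dict(energy_kj=2600, protein_g=0.2, fat_g=70, satfat_g=13,
        mufa_g=15, pufa_g=38, sodium_mg=650, retinol_ug=800, vitamin_e_mg=25,
        vitamin_d_ug=7.9, carotene_ug=300),
    "lowfat_spread": dict(energy_kj=1500, protein_g=5.8, fat_g=40,
        satfat_g=11, mufa_g=17, pufa_g=10, cholesterol_mg=6, sodium_mg=690,
        calcium_mg=33, retinol_ug=900, vitamin_e_mg=6.0, vitamin_d_ug=8.0,
        carotene_ug=300),
    "oil": dict(energy_kj=3700, fat_g=99.9, satfat_g=13, mufa_g=30,
        pufa_g=52, vitamin_e_mg=30),
    "milk_whole": dict(energy_kj=270, protein_g=3.3, fat_g=3.9, satfat_g=2.5,
        mufa_g=1.1, pufa_g=0.1, cholesterol_mg=14, carbohydrate_g=4.6,
        sugars_g=4.6, calcium_mg=115, potassium_mg=140, sodium_mg=55,
        phosphorus_mg=92, magnesium_mg=11, folate_ug=6, iron_mg=0.06,
        zinc_mg=0.4, vitamin_c_mg=1, thiamin_mg=0.03, riboflavin_mg=0.17,
        retinol_ug=52, vitamin_e_mg=0.09, vitamin_d_ug=0.03,
        vitamin_b6_mg=0.06, vitamin_b12_ug=0.4, niacin_mg=0.1,
        tryptophan_mg=1.3, carotene_ug=20, selenium_ug=1, iodine_ug=15),
    "milk_semi": dict(energy_kj=195, protein_g=3.3, fat_g=1.6, satfat_g=1.0,
        mufa_g=0.5, pufa_g=0.05, cholesterol_mg=7, carbohydrate_g=5.0,
        sugars_g=5.0, calcium_mg=120, potassium_mg=150, sodium_mg=55,
        phosphorus_mg=94, magnesium_mg=11, folate_ug=6, iron_mg=0.05,
        zinc_mg=0.4, vitamin_c_mg=1, thiamin_mg=0.04, riboflavin_mg=0.18,
        retinol_ug=21, vitamin_e_mg=0.04, vitamin_d_ug=0.01,
        vitamin_b6_mg=0.06, vitamin_b12_ug=0.4, niacin_mg=0.1,
        tryptophan_mg=1.3, carotene_ug=9, selenium_ug=1, iodine_ug=15),
    "milk_skim": dict(energy_kj=140, protein_g=3.3, fat_g=0.1, satfat_g=0.06,
        mufa_g=0.03, pufa_g=0.01, cholesterol_mg=2, carbohydrate_g=5.0,
        sugars_g=5.0, calcium_mg=120, potassium_mg=150, sodium_mg=55,
        phosphorus_mg=95, magnesium_mg=12, folate_ug=5, iron_mg=0.05,
        zinc_mg=0.4, vitamin_c_mg=1, thiamin_mg=0.04, riboflavin_mg=0.17,
        retinol_ug=1, vitamin_b6_mg=0.06, vitamin_b12_ug=0.4, niacin_mg=0.1,
        tryptophan_mg=1.3, selenium_ug=1, iodine_ug=15),
    "milk_goat": dict(energy_kj=300, protein_g=3.1, fat_g=4.5, satfat_g=3.0,
        mufa_g=1.1, pufa_g=0.15, cholesterol_mg=10, carbohydrate_g=4.4,
        sugars_g=4.4, calcium_mg=120, potassium_mg=170, sodium_mg=42,
        phosphorus_mg=90, magnesium_mg=13, folate_ug=1, iron_mg=0.12,
        zinc_mg=0.5, vitamin_c_mg=1, thiamin_mg=0.04, riboflavin_mg=0.13,
        retinol_ug=44, vitamin_e_mg=0.03, vitamin_d_ug=0.1,
        vitamin_b6_mg=0.06, vitamin_b12_ug=0.1, niacin_mg=0.3,
        tryptophan_mg=1.2, selenium_ug=1, iodine_ug=9),
    "milk_soya": dict(energy_kj=180, protein_g=2.9, fat_g=1.9, satfat_g=0.3,
        mufa_g=0.4, pufa_g=1.0, carbohydrate_g=0.8, sugars_g=0.2,
        calcium_mg=13, potassium_mg=60, sodium_mg=32, phosphorus_mg=47,
        magnesium_mg=15, folate_ug=18, iron_mg=0.4, zinc_mg=0.3,
        thiamin_mg=0.06, riboflavin_mg=0.27, vitamin_e_mg=0.7,
        vitamin_b6_mg=0.07, niacin_mg=0.1, tryptophan_mg=1.0, selenium_ug=1,
        iodine_ug=1),
    "sugar": dict(energy_kj=1680, carbohydrate_g=105, sugars_g=105,
        nmes_g=105),
}

#: question -> template category (first block the code appears under)
_QUESTION_CATEGORY = {
    "c1a": "processed_meat", "c1b": "processed_meat", "c1c": "red_meat",
    "c1d": "poultry_skin", "c1e": "offal", "c1f": "white_fish",
    "c1g": "oily_fish", "c1h": "shellfish", "c1i": "eggs", "c1j": "cheese",
    "c1k": "pizza", "c1l": "fried_potato", "c1m": "fried_potato",
    "c1n": "potato_plain", "c1o": "rice_pasta", "c1p": "rice_pasta",
    "c1q": "crisps", "c3a": "legumes", "c3b": "vegetables",
    "c3c": "vegetables", "c3d": "vegetables", "c3e": "carrots",
    "c3f": "vegetables", "c3g": "salad", "c3h": "fruit", "c3i": "fruit_juice",
    "c3j": "fruit_juice", "c3k": "pudding_cake", "c3l": "breakfast_cereal",
    "c3m": "breakfast_cereal", "c3n": "breakfast_cereal",
    "c3o": "pudding_cake", "c3p": "crispbread", "c3q": "biscuits",
    "c3r": "chocolate_bar", "c3s": "legumes", "c3t": "nuts",
    "c3u": "soy_products", "c3v": "soy_products", "c3w": "soy_products",
    "c3x": "chocolate", "c3y": "sweets", "c4": "soft_drink",
    "c7a": "bread_white", "c7b": "bread_brown", "c7c": "bread_wholemeal",
    "c7d": "bread_flat", "c8a_bread": "butter", "c8a_cooking": "animal_fat",
    "c8b": "margarine", "c8c": "pufa_spread", "c8d": "lowfat_spread",
    "c8e": "oil", "c8f": "oil", "c10a": "milk_whole", "c10b": "milk_semi",
    "c10c": "milk_skim", "c10d": "milk_whole", "c10f": "milk_goat",
    "c10g": "milk_soya", "sugar": "sugar",
}

#: per-code category overrides (lean cuts, specific foods)
_CODE_CATEGORY = {
    "387": "red_meat_lean", "413": "red_meat_lean", "422": "red_meat_lean",
    "356": "red_meat_lean", "438": "poultry_lean", "1037": "crisps",
    "755": "carrots", "76": "porridge",
    "15132": "curry", "15103": "curry", "15120": "curry",
    "14847": "tahini", "17009": "oil",
    "306": "butter", "335": "butter", "17007": "butter", "17013": "butter",
}

_JITTER = 0.15  # +/- relative spread of per-code densities around the template


def _jitter_factor(code: str, slot: str) -> float:
    """Deterministic per-(code, nutrient) factor in [1-_JITTER, 1+_JITTER].

    Seeded from a CRC32 of the key so the table is identical across
    platforms and sessions."""
    seed = zlib.crc32(f"{code}|{slot}".encode())
    u = np.random.default_rng(seed).random()
    return 1.0 - _JITTER + 2.0 * _JITTER * u


def synthetic_composition(portions: PortionTable | None = None) -> CompositionTable:
    """Build the packaged synthetic composition table.

    Every food code referenced by the portion table receives densities from
    its category template with deterministic per-code jitter.  Clearly
    synthetic: magnitudes are plausible, values are not database entries.
    """
    if portions is None:
        portions = packaged_portion_table()
    # code -> (description, category) from first appearance
    meta: dict[str, tuple[str, str]] = {}
    with resources.as_file(
        resources.files("ffqkit") / "data" / "portions_pregnancy.csv"
    ) as p:
        with open(p, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                code = str(rec["food_code"]).strip()
                if code in meta:
                    continue
                q = rec["question_id"].strip()
                cat = _CODE_CATEGORY.get(code, _QUESTION_CATEGORY.get(q))
                if cat is None:
                    raise PortionTableError(f"no category for question {q}")
                meta[code] = (rec.get("description", ""), cat)
    table = CompositionTable()
    for code in portions.food_codes():
        desc, cat = meta[code]
        template = _T[cat]
        dens = {}
        for slot in COMPOSITION_SLOTS:
            base = template.get(slot, 0.0)
            dens[slot] = round(base * _jitter_factor(code, slot), 6)
        table.add(code, f"{desc} [synthetic]", dens)
    return table
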