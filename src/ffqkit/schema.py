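"""FFQ questionnaire schema and participant-response data model.

The 32-week pregnancy FFQ asks the weekly frequency of 43 food groups on a
five-category scale, plus additional questions on eight daily basics
(bread, milk, fats, sugar, soft drinks, tea/coffee/cola) and food-related
behaviours.  Items are keyed by their cohort variable codes (c200-c318
range).  This module defines the item/scale model, the packaged pregnancy
schema, and response-level parsing with an explicit missing state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ItemDef",
    "FfqSchema",
    "FfqResponse",
    "SchemaError",
    "WEEKLY5_LABELS",
    "USE_LABELS",
    "normalise_label",
    "pregnancy_schema",
]


class SchemaError(ValueError):
    """A response or file does not conform to the questionnaire schema."""


#: The five weekly-frequency response options, in questionnaire order.
WEEKLY5_LABELS: tuple[str, ...] = (
    "Never or rarely",
    "Once in 2 weeks",
    "1-3 times a week",
    "4-7 times a week",
    "More than once a day",
)

#: Usually/sometimes/never options for milk types and milk uses.
USE_LABELS: tuple[str, ...] = ("Yes usually", "Yes sometimes", "No not at all")

_DASHES = re.compile(r"[‐-―−]")  # unicode dashes -> hyphen
_WS = re.compile(r"\s+")


def normalise_label(raw: str) -> str:
    """Canonicalise a category label for matching.

    Case-folded, whitespace collapsed, unicode dashes mapped to the ASCII
    hyphen, commas dropped, and "per week" treated as "a week" so that the
    questionnaire's printed options and common transcriptions compare equal.
    """
    s = _DASHES.sub("-", str(raw))
    s = s.replace(",", " ").replace("’", "'")
    s = _WS.sub(" ", s).strip().casefold()
    s = s.replace(" per week", " a week")
    return s


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item.

    ``scale`` is one of ``weekly5`` (five-category frequency), ``count``
    (a free number), ``categorical``, ``yesno`` or ``text``.
    ``portion_question`` links a weekly5 item to its block in the portion
    table (``None`` for behaviour-only items such as fried foods, which
    carry no food assignment).
    """

    code: str
    question_id: str
    question: str
    scale: str
    categories: tuple[str, ...] = ()
    portion_question: str | None = None
    behaviour_only: bool = False

    def __post_init__(self) -> None:
        if self.scale not in ("weekly5", "count", "categorical", "yesno", "text"):
            raise SchemaError(f"{self.code}: unknown scale {self.scale!r}")
        if self.scale == "weekly5" and tuple(self.categories) != WEEKLY5_LABELS:
            raise SchemaError(
                f"{self.code}: weekly5 items must carry the five standard labels"
            )


@dataclass
class FfqSchema:
    """An ordered collection of items with unique variable codes."""

    items: list[ItemDef]
    version: str = "pregnancy-32wk"

    def __post_init__(self) -> None:
        codes = [i.code for i in self.items]
        if len(codes) != len(set(codes)):
            raise SchemaError("duplicate item codes in schema")
        self._by_code = {i.code: i for i in self.items}
        # label -> canonical, per categorical item
        self._label_maps: dict[str, dict[str, str]] = {}
        for item in self.items:
            if item.categories:
                self._label_maps[item.code] = {
                    normalise_label(c): c for c in item.categories
                }

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> ItemDef:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemaError(f"unknown variable code: {code}") from None

    @property
    def codes(self) -> list[str]:
        return [i.code for i in self.items]

    def weekly5_codes(self) -> list[str]:
        return [i.code for i in self.items if i.scale == "weekly5"]

    def derivable_weekly5_codes(self) -> list[str]:
        """Weekly5 items that carry a food assignment (excludes behaviour-only)."""
        return [
            i.code
            for i in self.items
            if i.scale == "weekly5" and not i.behaviour_only
        ]

    def count_weekly_items(self) -> int:
        """Number of items on the five-category weekly frequency scale."""
        return len(self.weekly5_codes())

    def parse_answer(self, code: str, raw: object):
        """Parse one raw cell into the item's value domain.

        Returns ``None`` for missing (empty cell / NA).  Unparseable cells
        raise ``SchemaError``; callers decide whether to degrade to missing.
        """
        item = self[code]
        if raw is None:
            return None
        s = str(raw).strip()
        if s == "" or s.casefold() in ("na", "nan", "none", "."):
            return None
        if item.scale in ("weekly5", "categorical"):
            key = normalise_label(s)
            table = self._label_maps[code]
            if key not in table:
                raise SchemaError(f"{code}: unrecognised category {s!r}")
            return table[key]
        if item.scale == "yesno":
            key = s.casefold()
            if key in ("yes", "y", "1", "true"):
                return True
            if key in ("no", "n", "0", "false"):
                return False
            raise SchemaError(f"{code}: unrecognised yes/no value {s!r}")
        if item.scale == "count":
            return _parse_count(s, code)
        return s  # text


def _parse_count(s: str, code: str) -> float:
    """Parse a count cell; banded strings like "7-14 a day" give the band
    midpoint (downstream recodes apply any cap)."""
    try:
        return float(s)
    except ValueError:
        pass
    nums = re.findall(r"\d+(?:\.\d+)?", _DASHES.sub("-", s))
    if not nums:
        raise SchemaError(f"{code}: unparseable count {s!r}")
    vals = [float(x) for x in nums]
    return sum(vals) / len(vals)


@dataclass
class FfqResponse:
    """One participant's coded answers.

    ``answers`` maps variable code -> parsed value; missing answers are the
    explicit value ``None`` (never a silently-coerced empty string).  Keys
    must all appear in the schema used to load/validate the response.
    """

    participant_id: str
    answers: dict[str, object] = field(default_factory=dict)

    def get(self, code: str):
        return self.answers.get(code)


# ---------------------------------------------------------------------------
# Packaged 32-week pregnancy schema
# ---------------------------------------------------------------------------

# (code, question_id, question, portion_question, behaviour_only)
_WEEKLY5_ITEMS = [
    ("c200", "C1a", "Sausages, burgers", "c1a", False),
    ("c201", "C1b", "Pies, pasties", "c1b", False),
    ("c202", "C1c", "Meat (beef, lamb, pork, ham, bacon)", "c1c", False),
    ("c203", "C1d", "Poultry (chicken, turkey)", "c1d", False),
    ("c204", "C1e", "Liver, liver pate, kidney, heart", "c1e", False),
    ("c205", "C1f", "White fish (cod, haddock, plaice, fish fingers)", "c1f", False),
    ("c206", "C1g", "Other/oily fish (sardines, mackerel, tuna, salmon)", "c1g", False),
    ("c207", "C1h", "Shellfish (prawns, crab, cockles, mussels)", "c1h", False),
    ("c208", "C1i", "Eggs, quiche", "c1i", False),
    ("c209", "C1j", "Cheese", "c1j", False),
    ("c210", "C1k", "Pizza", "c1k", False),
    ("c211", "C1l", "Chips", "c1l", False),
    ("c215", "C1m", "Roast potatoes (cooked in fat)", "c1m", False),
    ("c216", "C1n", "Boiled, mashed, jacket potatoes", "c1n", False),
    ("c217", "C1o", "Rice (boiled)", "c1o", False),
    ("c218", "C1p", "Pasta", "c1p", False),
    ("c219", "C1q", "Crisps", "c1q", False),
    ("c220", "C1r", "Fried foods", None, True),
    ("c222", "C3a", "Baked beans", "c3a", False),
    ("c223", "C3b", "Peas, sweetcorn, broad beans", "c3b", False),
    ("c224", "C3c", "Cabbage, sprouts and other green leafy vegetables", "c3c", False),
    ("c225", "C3d", "Other green vegetables", "c3d", False),
    ("c226", "C3e", "Carrots", "c3e", False),
    ("c227", "C3f", "Other root vegetables", "c3f", False),
    ("c228", "C3g", "Salad", "c3g", False),
    ("c229", "C3h", "Fresh fruit", "c3h", False),
    ("c230", "C3i", "Tinned juice (including tomato juice)", "c3i", False),
    ("c231", "C3j", "Pure juice not in tin", "c3j", False),
    ("c232", "C3k", "Pudding", "c3k", False),
    ("c233", "C3l", "Oat cereals", "c3l", False),
    ("c234", "C3m", "Wholegrain or bran cereals", "c3m", False),
    ("c235", "C3n", "Other cereals", "c3n", False),
    ("c236", "C3o", "Cakes or buns", "c3o", False),
    ("c237", "C3p", "Crispbreads", "c3p", False),
    ("c238", "C3q", "Biscuits", "c3q", False),
    ("c239", "C3r", "Chocolate bars", "c3r", False),
    ("c240", "C3s", "Pulses", "c3s", False),
    ("c241", "C3t", "Nuts, nut roast", "c3t", False),
    ("c242", "C3u", "Bean curd (tofu, miso)", "c3u", False),
    ("c243", "C3v", "Tahini", "c3v", False),
    ("c244", "C3w", "Soya 'meat', TVP, vegeburgers", "c3w", False),
    ("c245", "C3x", "Chocolate", "c3x", False),
    ("c246", "C3y", "Sweets", "c3y", False),
]

FAT_ON_MEAT_LABELS = ("Yes, all of it", "Yes, some of it", "No", "Never eat meat")
DIET_DRINK_LABELS = ("Always", "Sometimes", "Not at all", "Don't drink soft drinks")
BREAD_SLICE_LABELS = ("Less than 1", "1-2", "3-4", "5 or more")
TAKEAWAY_LABELS = ("Never or rarely", "1-2", "3-4", "5-9", "10 or more")

#: milk type code -> portion-table question (dried/other have no block)
MILK_TYPE_PORTION = {
    "c276": "c10a",  # full fat
    "c277": "c10b",  # semi-skimmed
    "c278": "c10c",  # skimmed
    "c279": "c10d",  # sterilised
    "c280": None,    # dried milk: no composition block
    "c281": "c10f",  # goat/sheep
    "c282": "c10g",  # soya
    "c283": None,    # other
}

#: fat type letter -> (on-bread flag code, frying flag code)
FAT_TYPE_FLAGS = {
    "a": ("c260", "c266"),  # butter/ghee/dripping/lard
    "b": ("c261", "c267"),  # margarine
    "c": ("c262", "c268"),  # polyunsaturated fat spread
    "d": ("c263", "c269"),  # low fat spread
    "e": ("c264", "c270"),  # named oils
    "f": ("c265", "c271"),  # other vegetable oil
}

MILK_USE_CODES = {
    "tea": "c284",
    "coffee": "c285",
    "cereal": "c286",
    "pudding": "c287",
    "drink": "c288",
    "milky_drink": "c289",
}

BREAD_TYPE_PORTION = {
    "c252": "c7a",  # white
    "c253": "c7b",  # brown/granary
    "c254": "c7c",  # wholemeal
    "c255": "c7d",  # chapatti/naan
}
BREAD_NONE_CODE = "c256"  # "don't usually eat any bread"

DRINK_COUNT_CODES = {
    "tea_caff": "c300",
    "tea_decaf": "c301",
    "sugar_tea": "c302",
    "coffee_caff": "c304",
    "coffee_decaf": "c305",
    "sugar_coffee": "c306",
    "cola_caff": "c310",
    "cola_decaf": "c311",
}


def pregnancy_schema() -> FfqSchema:
    """Build the packaged 32-week pregnancy FFQ schema (43 weekly items
    plus the daily-basics and drink questions used by the derivation)."""
    items: list[ItemDef] = []
    for code, qid, q, pq, beh in _WEEKLY5_ITEMS:
        items.append(
            ItemDef(code, qid, q, "weekly5", WEEKLY5_LABELS, pq, behaviour_only=beh)
        )
    items.append(ItemDef("c221", "C2", "Do you eat all the fat on meat?",
                         "categorical", FAT_ON_MEAT_LABELS))
    items.append(ItemDef("c247", "C4", "How often do you choose diet drinks?",
                         "categorical", DIET_DRINK_LABELS))
    items.append(ItemDef("c250", "C5", "Pieces of bread per usual day",
                         "categorical", BREAD_SLICE_LABELS))
    items.append(ItemDef("c251", "C6", "Take-away meals per month",
                         "categorical", TAKEAWAY_LABELS, behaviour_only=True))
    for i, code in enumerate(BREAD_TYPE_PORTION):
        items.append(ItemDef(code, f"C7{'abcd'[i]}", "Bread type eaten most days",
                             "yesno"))
    items.append(ItemDef(BREAD_NONE_CODE, "C7e", "Doesn't usually eat bread",
                         "yesno"))
    for letter, (bread_code, fry_code) in FAT_TYPE_FLAGS.items():
        items.append(ItemDef(bread_code, f"C8i{letter}",
                             "Fat used on bread or vegetables", "yesno"))
        items.append(ItemDef(fry_code, f"C8ii{letter}",
                             "Fat used for frying", "yesno"))
    items.append(ItemDef("c275", "C9", "Slices of bread spread with fat per day",
                         "count"))
    for i, code in enumerate(MILK_TYPE_PORTION):
        items.append(ItemDef(code, f"C10{'abcdefgh'[i]}", "Milk type used",
                             "categorical", USE_LABELS))
    for i, (_use, code) in enumerate(MILK_USE_CODES.items()):
        items.append(ItemDef(code, f"C11{'abcdef'[i]}", "How often milk is used",
                             "categorical", USE_LABELS))
    for name, code in DRINK_COUNT_CODES.items():
        items.append(ItemDef(code, f"C12_{name}", "Drinks/sugar per day", "count"))
    return FfqSchema(items=items)
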