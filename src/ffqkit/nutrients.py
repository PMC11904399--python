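"""Named daily/weekly nutrient intake vectors.

The derivation produces one value per participant for each of 38 derived
quantities: energy, the macronutrient fractions, 21 vitamins and minerals,
the three fish fatty-acid estimates and caffeine.  Intakes are accumulated
on a weekly basis (frequencies are per week) and converted to daily by exact
division by 7.

Unit conventions (daily basis): energy kJ (reported also as MJ), protein/
fats/carbohydrate fractions g, cholesterol mg, minerals mg or µg, vitamins
mg or µg, fish n-3/EPA/DHA g, caffeine mg.  The tryptophan slot carries the
niacin-equivalent contribution (tryptophan/60, mg), so that
``niacin_equiv_mg = niacin_mg + tryptophan_mg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# Slots resolvable from a food-composition table (per 100 g densities).
COMPOSITION_SLOTS: tuple[str, ...] = (
    "energy_kj",
    "protein_g",
    "fat_g",
    "satfat_g",
    "mufa_g",
    "pufa_g",
    "cholesterol_mg",
    "carbohydrate_g",
    "starch_g",
    "sugars_g",
    "nmes_g",
    "nsp_g",
    "calcium_mg",
    "potassium_mg",
    "sodium_mg",
    "phosphorus_mg",
    "magnesium_mg",
    "folate_ug",
    "iron_mg",
    "zinc_mg",
    "vitamin_c_mg",
    "thiamin_mg",
    "riboflavin_mg",
    "retinol_ug",
    "vitamin_e_mg",
    "vitamin_d_ug",
    "vitamin_b6_mg",
    "vitamin_b12_ug",
    "niacin_mg",
    "tryptophan_mg",
    "carotene_ug",
    "selenium_ug",
    "iodine_ug",
)

# Derived and closed-form slots.
DERIVED_SLOTS: tuple[str, ...] = (
    "niacin_equiv_mg",
    "n3_fish_g",
    "epa_fish_g",
    "dha_fish_g",
    "caffeine_mg",
)

ALL_SLOTS: tuple[str, ...] = COMPOSITION_SLOTS + DERIVED_SLOTS

#: Slots removed as a block when any plausibility rule fires.  The fish
#: fatty-acid stream is screened independently; caffeine follows the main
#: nutrient file.
MAIN_STREAM_SLOTS: tuple[str, ...] = tuple(
    s for s in ALL_SLOTS if s not in ("n3_fish_g", "epa_fish_g", "dha_fish_g")
)
FISH_STREAM_SLOTS: tuple[str, ...] = ("n3_fish_g", "epa_fish_g", "dha_fish_g")


class BasisError(ValueError):
    """Raised when an operation receives a vector on the wrong basis."""


@dataclass
class NutrientVector:
    """One participant's intake across all derived slots.

    Parameters
    ----------
    values : dict
        Slot name -> amount.  Every slot of :data:`ALL_SLOTS` is present;
        missing slots are initialised to 0.
    basis : str
        ``"weekly"`` or ``"daily"``.
    """

    values: dict[str, float] = field(default_factory=dict)
    basis: str = "weekly"

    def __post_init__(self) -> None:
        if self.basis not in ("weekly", "daily"):
            raise BasisError(f"basis must be 'weekly' or 'daily', got {self.basis!r}")
        unknown = set(self.values) - set(ALL_SLOTS)
        if unknown:
            raise KeyError(f"unknown nutrient slots: {sorted(unknown)}")
        for slot in ALL_SLOTS:
            self.values.setdefault(slot, 0.0)

    def __getitem__(self, slot: str) -> float:
        return self.values[slot]

    def __setitem__(self, slot: str, amount: float) -> None:
        if slot not in ALL_SLOTS:
            raise KeyError(f"unknown nutrient slot: {slot}")
        self.values[slot] = float(amount)

    def add(self, slot: str, amount: float) -> None:
        self[slot] = self.values[slot] + float(amount)

    @property
    def energy_mj(self) -> float:
        return self.values["energy_kj"] / 1000.0

    def is_finite_nonnegative(self) -> bool:
        return all(math.isfinite(v) and v >= 0 for v in self.values.values())

    def to_daily(self) -> "NutrientVector":
        """Exact division by 7; see :func:`ffqkit.derivation.to_daily`."""
        if self.basis != "weekly":
            raise BasisError("vector is already on a daily basis")
        return NutrientVector(
            values={k: v / 7.0 for k, v in self.values.items()}, basis="daily"
        )

    def copy(self) -> "NutrientVector":
        return NutrientVector(values=dict(self.values), basis=self.basis)
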