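"""Derivation constants, all overridable through a JSON config.

Every printed constant of the derivation (frequency weights, version-6
recodes, fish and caffeine per-portion values, energy-conversion factors)
defaults to its published value here; quantities the derivation needs but
whose values were never printed (per-slice spread weight, per-use milk
volumes, sugar spoon weight, EPA/DHA per-portion splits, the basal
metabolic rate and activity constants of the misreporter screen) carry
clearly-labelled package defaults and live in the same config so a user can
substitute their own.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

__all__ = ["FishConstants", "CaffeineConstants", "MisreportConstants",
           "DerivationConstants", "load_constants"]


class FishConstants(BaseModel):
    """Per-portion fatty-acid content (g) for the three seafood questions.

    The n-3 values are the published per-portion estimates; the EPA/DHA
    splits are package defaults (not published) chosen so that DHA exceeds
    EPA at the population level and EPA + DHA never exceeds total n-3.
    """

    n3_per_portion: dict[str, float] = Field(
        default={"white": 0.32, "oily": 0.89, "shellfish": 0.35}
    )
    epa_per_portion: dict[str, float] = Field(
        default={"white": 0.06, "oily": 0.26, "shellfish": 0.12}
    )
    dha_per_portion: dict[str, float] = Field(
        default={"white": 0.16, "oily": 0.45, "shellfish": 0.13}
    )

    @model_validator(mode="after")
    def _check(self) -> "FishConstants":
        for cls in self.n3_per_portion:
            n3 = self.n3_per_portion[cls]
            epa = self.epa_per_portion.get(cls, 0.0)
            dha = self.dha_per_portion.get(cls, 0.0)
            if n3 <= 0 or epa <= 0 or dha <= 0:
                raise ValueError("per-portion constants must be strictly positive")
            if epa + dha > n3 + 1e-12:
                raise ValueError(f"EPA + DHA exceeds n-3 for class {cls!r}")
        return self


class CaffeineConstants(BaseModel):
    """mg caffeine per caffeinated drink."""

    mg_per_cup_tea: float = 27.0
    mg_per_cup_coffee: float = 57.0
    mg_per_cola: float = 20.0

    @model_validator(mode="after")
    def _check(self) -> "CaffeineConstants":
        if min(self.mg_per_cup_tea, self.mg_per_cup_coffee, self.mg_per_cola) <= 0:
            raise ValueError("caffeine constants must be strictly positive")
        return self


class MisreportConstants(BaseModel):
    """Predicted-energy-requirement screen (standard literature values,
    config-stored: Schofield BMR band for women 18-29 y, a fixed physical
    activity level, and Goldberg-style plausibility bounds on the
    reported/predicted ratio)."""

    schofield_slope_mj_per_kg: float = 0.062
    schofield_intercept_mj: float = 2.036
    pal: float = 1.4
    ratio_lower: float = 0.54
    ratio_upper: float = 2.0


class DerivationConstants(BaseModel):
    """All tunable constants of the nutrient-derivation engine."""

    # Published weekly-frequency weights for the five response categories.
    frequency_weights: dict[str, float] = Field(
        default={
            "Never or rarely": 0.0,
            "Once in 2 weeks": 0.5,
            "1-3 times a week": 2.0,
            "4-7 times a week": 5.5,
            "More than once a day": 10.0,
        }
    )
    # Bread slices/day from the four response bands; version-6 recode gives
    # missing the average amount, 1.5.
    bread_slices_map: dict[str, float] = Field(
        default={"Less than 1": 0.5, "1-2": 1.5, "3-4": 3.5, "5 or more": 5.5}
    )
    bread_slices_missing: float = 1.5
    # Version-6 recodes for slices spread with fat: missing -> 2, cap at 6.
    spread_slices_missing: float = 2.0
    spread_slices_max: float = 6.0
    # Soft drinks carry no frequency question; the modal frequency from the
    # later 47-month FFQ (2/week) is imposed, scaled by the diet-drink answer.
    soft_drink_per_week: float = 2.0
    diet_drink_scale: dict[str, float] = Field(
        default={
            "Always": 0.0,
            "Sometimes": 0.5,
            "Not at all": 1.0,
            "Don't drink soft drinks": 0.0,
        }
    )
    # Package defaults (not published): amounts behind the daily basics.
    spread_g_per_slice: float = 7.0
    sugar_g_per_spoon: float = 5.0
    milk_ml_per_use: dict[str, float] = Field(
        default={
            "tea": 30.0,
            "coffee": 30.0,
            "cereal": 100.0,
            "pudding": 100.0,
            "drink": 200.0,
            "milky_drink": 200.0,
        }
    )
    # Energy conversion factors, kJ per g, for percent-energy standardisation.
    energy_kj_per_g: dict[str, float] = Field(
        default={"protein_g": 17.0, "fat_g": 37.0, "carbohydrate_g": 16.0}
    )
    aoac_per_nsp: float = 1.33
    fish: FishConstants = Field(default_factory=FishConstants)
    caffeine: CaffeineConstants = Field(default_factory=CaffeineConstants)
    misreport: MisreportConstants = Field(default_factory=MisreportConstants)

    @model_validator(mode="after")
    def _check(self) -> "DerivationConstants":
        ordered = ["Never or rarely", "Once in 2 weeks", "1-3 times a week",
                   "4-7 times a week", "More than once a day"]
        w = [self.frequency_weights[k] for k in ordered]
        if any(b < a for a, b in zip(w, w[1:])) or any(x < 0 for x in w):
            raise ValueError("frequency weights must be non-negative and "
                             "monotone non-decreasing across categories")
        return self


def load_constants(path: str | Path | None = None) -> DerivationConstants:
    """Load constants, overriding defaults with any keys present in the
    JSON file at ``path`` (deep merge at the top two levels)."""
    base = DerivationConstants()
    if path is None:
        return base
    overrides = json.loads(Path(path).read_text())
    data = base.model_dump()
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **val}
        else:
            data[key] = val
    return DerivationConstants(**data)
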