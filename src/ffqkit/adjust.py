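"""Derived-score utilities: fibre conversion, energy standardisation and
misreporter screening."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .constants import DerivationConstants, MisreportConstants
from .nutrients import ALL_SLOTS, BasisError, NutrientVector

log = logging.getLogger(__name__)

__all__ = ["aoac_from_nsp", "energy_standardise", "flag_misreporters",
           "MisreportFlag"]


def aoac_from_nsp(nsp_g: float) -> float:
    """AOAC (enzymatic-gravimetric) fibre from NSP fibre: NSP x 1.33."""
    if nsp_g < 0:
        raise ValueError("NSP intake cannot be negative")
    return nsp_g * 1.33


def energy_standardise(
    vector: NutrientVector,
    mode: str = "percent",
    constants: DerivationConstants | None = None,
) -> dict[str, float]:
    """Standardise a daily intake vector for energy.

    ``percent`` expresses each energy-yielding macronutrient as a
    percentage of energy intake (g x kJ/g conversion factor / energy kJ
    x 100; factors: protein 17, fat 37, carbohydrate 16 kJ/g).
    ``density`` expresses every slot per MJ of energy.
    """
    c = constants or DerivationConstants()
    if vector.basis != "daily":
        raise BasisError("energy standardisation expects a daily vector")
    energy_kj = vector["energy_kj"]
    if energy_kj <= 0:
        raise ValueError("energy intake must be positive to standardise")
    if mode == "percent":
        return {
            slot: vector[slot] * factor / energy_kj * 100.0
            for slot, factor in c.energy_kj_per_g.items()
        }
    if mode == "density":
        mj = energy_kj / 1000.0
        return {slot: vector[slot] / mj for slot in ALL_SLOTS if slot != "energy_kj"}
    raise ValueError(f"unknown standardisation mode {mode!r}")


@dataclass(frozen=True)
class MisreportFlag:
    """Outcome of the predicted-energy-requirement screen for one woman."""

    participant_id: str
    predicted_mj: float | None
    ratio: float | None
    category: str                 # plausible / under / over
    ratio_lower: float
    ratio_upper: float


def flag_misreporters(
    energy_daily_mj: float,
    pre_pregnancy_weight_kg: float | None,
    pal: float | None = None,
    constants: MisreportConstants | None = None,
    participant_id: str = "",
) -> MisreportFlag:
    """Classify reported energy against an individualised predicted
    requirement.

    The requirement is basal metabolic rate (Schofield equation for women
    18-29 y: 0.062 x weight + 2.036 MJ/day) times a standard physical
    activity level; the reported/predicted ratio is classed under/
    plausible/over against Goldberg-style bounds.  A missing weight yields
    "plausible" with a logged caveat rather than an error.
    """
    c = constants or MisreportConstants()
    pal = c.pal if pal is None else pal
    if pre_pregnancy_weight_kg is None or (
        isinstance(pre_pregnancy_weight_kg, float)
        and math.isnan(pre_pregnancy_weight_kg)
    ):
        log.warning("participant %s: no pre-pregnancy weight; misreporter "
                    "screen inconclusive, classed plausible", participant_id)
        return MisreportFlag(participant_id, None, None, "plausible",
                             c.ratio_lower, c.ratio_upper)
    if pre_pregnancy_weight_kg <= 0:
        raise ValueError("pre-pregnancy weight must be positive")
    bmr = (c.schofield_slope_mj_per_kg * pre_pregnancy_weight_kg
           + c.schofield_intercept_mj)
    predicted = bmr * pal
    ratio = energy_daily_mj / predicted
    if ratio < c.ratio_lower:
        category = "under"
    elif ratio > c.ratio_upper:
        category = "over"
    else:
        category = "plausible"
    return MisreportFlag(participant_id, predicted, ratio, category,
                         c.ratio_lower, c.ratio_upper)
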