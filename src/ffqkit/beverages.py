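"""Closed-form estimators for fish fatty acids and caffeine.

Fish n-3 intake comes from the three seafood frequency questions: each
class (white fish, oily fish, shellfish) contributes its weekly frequency
times a fixed per-portion fatty-acid content (n-3: 0.32, 0.89 and 0.35 g
respectively), summed and divided by 7 for a daily value.  EPA and DHA use
the same form with per-portion constants of their own.

Weekly caffeine is 7 x (caffeinated tea cups x 27 mg + coffee cups x 57 mg
+ colas x 20 mg); decaffeinated drinks contribute nothing.
"""

from __future__ import annotations

from .constants import CaffeineConstants, FishConstants

__all__ = ["fish_fatty_acids", "caffeine_weekly", "average_weekday_weekend"]


def fish_fatty_acids(
    freq_white: float,
    freq_oily: float,
    freq_shellfish: float,
    constants: FishConstants | None = None,
) -> tuple[float, float, float]:
    """Daily (n-3, EPA, DHA) grams from recoded weekly seafood frequencies."""
    c = constants or FishConstants()
    freqs = {"white": freq_white, "oily": freq_oily, "shellfish": freq_shellfish}
    for cls, f in freqs.items():
        if f < 0:
            raise ValueError(f"negative weekly frequency for {cls} fish: {f}")
    n3 = sum(f * c.n3_per_portion[cls] for cls, f in freqs.items())
    epa = sum(f * c.epa_per_portion[cls] for cls, f in freqs.items())
    dha = sum(f * c.dha_per_portion[cls] for cls, f in freqs.items())
    return n3 / 7.0, epa / 7.0, dha / 7.0


def caffeine_weekly(
    cups_tea_per_day: float,
    cups_coffee_per_day: float,
    colas_per_day: float,
    constants: CaffeineConstants | None = None,
) -> float:
    """Weekly caffeine (mg) from CAFFEINATED daily drink counts.

    Callers pass the caffeinated counts only; decaffeinated drinks are
    accounted for upstream by not being counted here.
    """
    c = constants or CaffeineConstants()
    cups_tea = max(float(cups_tea_per_day), 0.0)
    cups_coffee = max(float(cups_coffee_per_day), 0.0)
    colas = max(float(colas_per_day), 0.0)
    return 7.0 * (cups_tea * c.mg_per_cup_tea
                  + cups_coffee * c.mg_per_cup_coffee
                  + colas * c.mg_per_cola)


def average_weekday_weekend(weekday: float, weekend: float) -> float:
    """Collapse separate weekday/weekend daily counts (earlier-gestation
    questionnaires) to one daily rate: (5 x weekday + 2 x weekend) / 7."""
    return (5.0 * weekday + 2.0 * weekend) / 7.0
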