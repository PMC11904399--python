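"""Frequency recoding, daily basics, weekly summation and exclusions."""

import numpy as np
import pytest

import ffqkit as fk
from ffqkit.derivation import (
    ExclusionRule,
    apply_exclusions,
    recode_frequency,
    resolve_basics,
)
from ffqkit.nutrients import ALL_SLOTS, BasisError, COMPOSITION_SLOTS, NutrientVector
from ffqkit.reference import brute_force_weekly
from ffqkit.schema import WEEKLY5_LABELS


class TestRecodeFrequency:
    @pytest.mark.parametrize(
        "label,weight",
        [
            ("Never or rarely", 0.0),
            ("Once in 2 weeks", 0.5),
            ("1-3 times a week", 2.0),
            ("4-7 times per week", 5.5),
            ("More than once a day", 10.0),
        ],
    )
    def test_published_weights(self, label, weight):
        assert recode_frequency(label) == weight

    def test_missing_is_never_eaten(self):
        assert recode_frequency(None) == 0.0

    def test_unknown_label_is_error(self):
        with pytest.raises(ValueError, match="unknown frequency"):
            recode_frequency("every blue moon")

    def test_weights_monotone_across_categories(self):
        weights = [recode_frequency(lbl) for lbl in WEEKLY5_LABELS]
        assert weights == sorted(weights)


class TestResolveBasics:
    def test_missing_bread_slices_recoded_to_1p5(self, make_response):
        assert resolve_basics(make_response()).bread_slices_per_day == 1.5

    @pytest.mark.parametrize(
        "cat,slices",
        [("Less than 1", 0.5), ("1-2", 1.5), ("3-4", 3.5), ("5 or more", 5.5)],
    )
    def test_bread_slice_bands(self, make_response, cat, slices):
        b = resolve_basics(make_response({"c250": cat}))
        assert b.bread_slices_per_day == slices

    def test_missing_spread_slices_recoded_to_2(self, make_response):
        assert resolve_basics(make_response()).spread_slices_per_day == 2.0

    def test_spread_slices_capped_at_6(self, make_response, schema):
        # the banded answer "7-14 a day" parses to its midpoint, then caps
        raw = schema.parse_answer("c275", "7–14 a day")
        b = resolve_basics(make_response({"c275": raw}))
        assert b.spread_slices_per_day == 6.0

    def test_milk_shares_usually_vs_sometimes(self, make_response):
        b = resolve_basics(make_response({
            "c276": "Yes usually", "c278": "Yes sometimes"}))
        assert b.milk_type_shares == pytest.approx(
            {"c10a": 2 / 3, "c10c": 1 / 3})

    def test_no_types_ticked_gives_national_defaults(self, make_response):
        b = resolve_basics(make_response())
        assert b.bread_shares == {"c7a": 1.0}        # white bread
        assert b.milk_type_shares == {"c10a": 1.0}   # whole milk
        assert b.fat_spread_shares == {"c8b": 1.0}   # soft margarine
        assert b.fat_cooking_shares == {"c8f": 1.0}  # blended vegetable oil

    def test_explicit_no_bread_zeroes_bread(self, make_response):
        b = resolve_basics(make_response({"c256": True}))
        assert b.bread_slices_per_day == 0.0
        assert b.bread_shares == {}

    def test_soft_drink_frequency_fixed_at_2_per_week(self, make_response):
        b = resolve_basics(make_response({"c247": "Not at all"}))
        assert b.soft_drinks_per_week == 2.0
        assert b.sugary_drink_scale == 1.0

    @pytest.mark.parametrize(
        "answer,scale",
        [("Always", 0.0), ("Sometimes", 0.5), ("Not at all", 1.0),
         ("Don't drink soft drinks", 0.0), (None, 0.0)],
    )
    def test_diet_drink_scaling(self, make_response, answer, scale):
        b = resolve_basics(make_response({"c247": answer}))
        assert b.sugary_drink_scale == scale

    def test_total_on_fully_missing_response(self, make_response):
        b = resolve_basics(make_response())
        assert b.cups_tea == 0.0 and b.sugar_spoons_tea == 0.0


class TestWeeklyNutrients:
    def test_all_missing_response_gets_basics_defaults_only(
        self, engine, make_response
    ):
        wk = engine.weekly_nutrients(make_response())
        # expected: 1.5 white-bread slices/day and 2 margarine-spread
        # slices/day, no milk uses, no drinks, no weekly items
        expected = (1.5 * 7.0 * engine.question_amounts("c7a")
                    + 2.0 * 7.0 * 7.0 / 100.0 * engine.question_amounts("c8b"))
        for i, slot in enumerate(COMPOSITION_SLOTS):
            assert wk[slot] == pytest.approx(expected[i], abs=1e-12)
        assert wk["caffeine_mg"] == 0.0 and wk["n3_fish_g"] == 0.0

    def test_single_food_contribution_is_freq_times_portion(
        self, engine, make_response, composition
    ):
        base = engine.weekly_nutrients(make_response())
        wk = engine.weekly_nutrients(
            make_response({"c219": "1-3 times a week"}))
        # crisps: one 27 g food; weekly n = 2 x 27/100 x density
        for slot in COMPOSITION_SLOTS:
            expected = 2.0 * 27.0 / 100.0 * composition.density("1037", slot)
            assert wk[slot] - base[slot] == pytest.approx(expected, abs=1e-9)

    def test_fat_on_meat_no_uses_lean_only_codes(
        self, engine, make_response, composition
    ):
        base = engine.weekly_nutrients(make_response({"c221": "No"}))
        wk = engine.weekly_nutrients(
            make_response({"c221": "No", "c202": "1-3 times a week"}))
        lean = {"387": 23.0, "413": 23.0, "422": 30.0, "356": 12.0}
        expected_fat = 2.0 * sum(
            g / 100.0 * composition.density(c, "fat_g") for c, g in lean.items())
        assert wk["fat_g"] - base["fat_g"] == pytest.approx(expected_fat)

    def test_monotone_in_frequency_category(self, engine, make_response):
        prev = None
        for label in WEEKLY5_LABELS:
            wk = engine.weekly_nutrients(make_response({"c209": label}))
            vals = np.array([wk[s] for s in ALL_SLOTS])
            if prev is not None:
                assert np.all(vals >= prev - 1e-12)
            prev = vals

    def test_matches_brute_force_oracle(self, engine, schema, small_cohort):
        responses, _ = small_cohort
        for resp in responses[:40]:
            wk = engine.weekly_nutrients(resp)
            ref = brute_force_weekly(resp, engine.portions, engine.composition,
                                     schema)
            for slot in ALL_SLOTS:
                denom = max(abs(ref[slot]), 1e-12)
                assert abs(wk[slot] - ref[slot]) / denom < 1e-9

    def test_bit_identical_on_repeat(self, engine, small_cohort):
        responses, _ = small_cohort
        a = engine.weekly_nutrients(responses[0])
        b = engine.weekly_nutrients(responses[0])
        assert a.values == b.values

    def test_all_slots_finite_nonnegative(self, engine, small_cohort):
        responses, _ = small_cohort
        for resp in responses[:40]:
            assert engine.weekly_nutrients(resp).is_finite_nonnegative()


def _midrange_weekly():
    """A weekly vector comfortably inside every plausibility bound."""
    v = NutrientVector(basis="weekly")
    v["energy_kj"] = 50000.0
    for rule in fk.load_exclusion_rules():
        if rule.name != "energy":
            v[rule.slot] = rule.upper / 2.0 * 7.0
    return v


class TestExclusions:
    def test_low_weekly_energy_excluded(self):
        v = _midrange_weekly()
        v["energy_kj"] = 14000.0
        kept, names = apply_exclusions(v, fk.load_exclusion_rules())
        assert not kept and names == ["energy_low"]

    def test_high_daily_retinol_excluded(self):
        v = _midrange_weekly()
        v["retinol_ug"] = 9000.0 * 7.0  # 9000 ug/day, above the 8000 cap
        kept, names = apply_exclusions(v, fk.load_exclusion_rules())
        assert not kept and names == ["retinol_high"]

    def test_midrange_record_kept(self):
        kept, names = apply_exclusions(_midrange_weekly(),
                                       fk.load_exclusion_rules())
        assert kept and names == []

    def test_daily_vector_rejected(self):
        with pytest.raises(BasisError):
            apply_exclusions(NutrientVector(basis="daily"),
                             fk.load_exclusion_rules())

    def test_rule_with_unknown_slot_is_config_error(self):
        with pytest.raises(ValueError, match="unknown nutrient slot"):
            ExclusionRule(name="x", slot="unobtainium_mg", upper=1.0)

    def test_rule_bounds_must_be_ordered(self):
        with pytest.raises(ValueError, match="lower bound"):
            ExclusionRule(name="x", slot="energy_kj", lower=10.0, upper=5.0)

    def test_select_if_chain_removes_whole_record(self, small_cohort):
        responses, _ = small_cohort
        result = fk.derive_cohort(responses)
        for pid in result.exclusions:
            assert pid not in result.kept.index


class TestToDaily:
    def test_weekly_energy_to_mj_per_day(self):
        v = NutrientVector(basis="weekly")
        v["energy_kj"] = 50610.0
        assert v.to_daily().energy_mj == pytest.approx(7.23)

    def test_weekly_protein_division(self):
        v = NutrientVector(basis="weekly")
        v["protein_g"] = 485.1
        assert v.to_daily()["protein_g"] == pytest.approx(69.3)

    def test_zero_vector_stays_zero(self):
        d = NutrientVector(basis="weekly").to_daily()
        assert all(x == 0.0 for x in d.values.values())

    def test_already_daily_is_contract_error(self):
        with pytest.raises(BasisError):
            NutrientVector(basis="daily").to_daily()
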