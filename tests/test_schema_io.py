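"""Schema model, response parsing and delimited-text round trips."""

import math

import pytest

import ffqkit as fk
from ffqkit.io import (
    exclusion_log_path,
    load_nutrients,
    load_responses,
    write_nutrients,
    write_responses,
)
from ffqkit.nutrients import ALL_SLOTS, NutrientVector
from ffqkit.schema import (
    DRINK_COUNT_CODES,
    FAT_TYPE_FLAGS,
    MILK_TYPE_PORTION,
    MILK_USE_CODES,
    FfqSchema,
    ItemDef,
    SchemaError,
    WEEKLY5_LABELS,
)


class TestSchema:
    def test_exactly_43_weekly_frequency_items(self, schema):
        assert schema.count_weekly_items() == 43

    def test_empty_schema_has_zero_weekly_items(self):
        assert FfqSchema(items=[]).count_weekly_items() == 0

    def test_weekly_codes_match_questionnaire_blocks(self, schema):
        codes = schema.weekly5_codes()
        expected = (
            [f"c{i}" for i in range(200, 212)]
            + [f"c{i}" for i in range(215, 221)]
            + [f"c{i}" for i in range(222, 247)]
        )
        assert codes == expected

    def test_fried_foods_item_is_behaviour_only(self, schema):
        assert "c220" not in schema.derivable_weekly5_codes()
        assert len(schema.derivable_weekly5_codes()) == 42

    def test_all_inscope_variable_codes_representable(self, schema):
        required = set(schema.weekly5_codes())
        required |= {"c221", "c247", "c250", "c251", "c275"}
        required |= set(MILK_TYPE_PORTION) | set(MILK_USE_CODES.values())
        required |= {c for pair in FAT_TYPE_FLAGS.values() for c in pair}
        required |= {"c252", "c253", "c254", "c255", "c256"}
        required |= set(DRINK_COUNT_CODES.values())
        for code in required:
            assert code in schema

    def test_weekly5_items_must_carry_standard_labels(self):
        with pytest.raises(SchemaError):
            ItemDef("c900", "X1", "bad", "weekly5", ("yes", "no"))

    def test_duplicate_codes_rejected(self, schema):
        item = schema["c200"]
        with pytest.raises(SchemaError):
            FfqSchema(items=[item, item])


class TestAnswerParsing:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("never or rarely", "Never or rarely"),
            ("NEVER OR RARELY", "Never or rarely"),
            ("1–3 times a week", "1-3 times a week"),  # en dash
            ("1-3 times per week", "1-3 times a week"),
            ("4-7 times a week", "4-7 times a week"),
            ("", None),
            ("NA", None),
        ],
    )
    def test_weekly5_label_matching(self, schema, raw, expected):
        assert schema.parse_answer("c200", raw) == expected

    def test_unknown_label_is_schema_error(self, schema):
        with pytest.raises(SchemaError):
            schema.parse_answer("c200", "twice a fortnight maybe")

    def test_banded_count_takes_midpoint(self, schema):
        assert schema.parse_answer("c275", "7–14 a day") == 10.5

    def test_plain_count(self, schema):
        assert schema.parse_answer("c275", "3") == 3.0

    def test_yesno(self, schema):
        assert schema.parse_answer("c252", "Yes") is True
        assert schema.parse_answer("c252", "no") is False


class TestResponseIO:
    def test_two_row_round_trip(self, schema, tmp_path):
        p = tmp_path / "resp.csv"
        p.write_text(
            "participant_id,c200,c250,c275\n"
            "A1,Never or rarely,1-2,3\n"
            "A2,1-3 times a week,,\n"
        )
        resp = load_responses(p, schema)
        assert len(resp) == 2
        assert resp[0].answers["c200"] == "Never or rarely"
        assert resp[1].answers["c250"] is None
        assert resp[0].answers["c275"] == 3.0

    def test_unknown_column_named_in_error(self, schema, tmp_path):
        p = tmp_path / "resp.csv"
        p.write_text("participant_id,c999\nA1,Never or rarely\n")
        with pytest.raises(SchemaError, match="c999"):
            load_responses(p, schema)

    def test_duplicate_participant_id_rejected(self, schema, tmp_path):
        p = tmp_path / "resp.csv"
        p.write_text("participant_id,c200\nA1,\nA1,\n")
        with pytest.raises(ValueError, match="A1"):
            load_responses(p, schema)

    def test_unparseable_cell_becomes_missing_with_warning(
        self, schema, tmp_path, caplog
    ):
        p = tmp_path / "resp.csv"
        p.write_text("participant_id,c200\nA1,gibberish answer\n")
        with caplog.at_level("WARNING"):
            resp = load_responses(p, schema)
        assert resp[0].answers["c200"] is None
        assert "treated as missing" in caplog.text

    def test_write_then_load_is_identity(self, schema, tmp_path, small_cohort):
        responses, _ = small_cohort
        p = tmp_path / "resp.csv"
        write_responses(responses[:25], schema, p)
        back = load_responses(p, schema)
        p2 = tmp_path / "resp2.csv"
        write_responses(back, schema, p2)
        assert p.read_text() == p2.read_text()
        for a, b in zip(responses[:25], back):
            assert a.participant_id == b.participant_id
            for code in schema.codes:
                assert a.answers.get(code) == b.answers.get(code)


class TestNutrientIO:
    def _vec(self, basis="daily", energy=7000.0):
        v = NutrientVector(basis=basis)
        v["energy_kj"] = energy
        v["protein_g"] = 69.123456789012
        return v

    def test_round_trip_to_12_significant_digits(self, tmp_path):
        p = tmp_path / "nut.csv"
        write_nutrients([("A1", self._vec())], p)
        df = load_nutrients(p)
        for slot in ALL_SLOTS:
            expected = self._vec()[slot]
            got = df.loc["A1", slot]
            if expected == 0:
                assert got == 0
            else:
                assert math.isclose(got, expected, rel_tol=1e-12)

    def test_empty_record_list_gives_header_only(self, tmp_path):
        p = tmp_path / "nut.csv"
        write_nutrients([], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("participant_id,")

    def test_excluded_record_goes_to_log_not_main_file(self, tmp_path):
        p = tmp_path / "nut.csv"
        # violates the weekly energy floor -> flagged upstream
        bad = NutrientVector(basis="weekly")
        bad["energy_kj"] = 14000.0
        kept, names = fk.apply_exclusions(bad, fk.load_exclusion_rules())
        assert not kept
        write_nutrients([("A1", bad)], p, exclusions={"A1": names})
        assert "A1" not in p.read_text()
        log = exclusion_log_path(p).read_text()
        assert "A1" in log and "energy_low" in log

    def test_mixed_bases_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="bases"):
            write_nutrients(
                [("A1", self._vec("daily")), ("A2", self._vec("weekly"))],
                tmp_path / "nut.csv",
            )

    def test_daily_file_reports_energy_in_mj(self, tmp_path):
        p = tmp_path / "nut.csv"
        write_nutrients([("A1", self._vec(energy=7230.0))], p)
        assert load_nutrients(p).loc["A1", "energy_mj"] == pytest.approx(7.23)
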