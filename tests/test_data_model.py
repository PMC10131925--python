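"""Parsing, imputation and one-hot encoding of tracking logs."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_encounter, make_patient
from pn_sdoh.data_model import (
    MISSING,
    ImputationError,
    ReferentialError,
    SchemaError,
    impute_missing,
    one_hot_decode,
    one_hot_encode,
    parse_tracking_log,
    patients_to_frame,
    write_tracking_log,
)


def _demo_frame(rows):
    cols = [
        "patient_id", "age", "occupation", "marital_status", "education_level",
        "year_arrived_us", "english_level", "origin", "zip_code",
        "household_size", "born_in_us", "income_range", "site",
    ]
    return pd.DataFrame(rows, columns=cols).astype(str)


def _enc_frame(rows):
    cols = [
        "patient_id", "date", "preferred_language", "all_languages",
        "service_type", "channel", "action_length", "action_taken",
        "comments", "sdoh_codes",
    ]
    return pd.DataFrame(rows, columns=cols).astype(str)


@pytest.fixture
def small_tables():
    demo = _demo_frame(
        [
            ["P1", "40", "retired", "married", "primary", "1990", "poor",
             "china", "60616", "3", "no", "lt_10k", "A"],
            ["P2", "50", "homemaker", "single", "secondary", "1985", "none",
             "china", "60608", "2", "no", "10k_20k", "A"],
        ]
    )
    enc = _enc_frame(
        [
            ["P1", "2014-01-01", "cantonese", "cantonese", "screening", "phone",
             "20", "referral", "called patient", "language_interpreter"],
            ["P1", "2014-01-08", "cantonese", "cantonese", "follow_up", "phone",
             "15", "referral", "", "fear;transportation"],
            ["P2", "2014-01-02", "mandarin", "mandarin", "screening", "in_person",
             "30", "education_materials", "visit note", "language_interpreter"],
        ]
    )
    return demo, enc


class TestParse:
    def test_two_patients_three_encounters_linked(self, small_tables):
        patients, encounters = parse_tracking_log(*small_tables)
        assert [p.patient_id for p in patients] == ["P1", "P2"]
        assert [e.patient_id for e in encounters] == ["P1", "P1", "P2"]
        assert encounters[1].sdoh_codes == ["fear", "transportation"]

    def test_empty_comments_cell_parses_as_absent(self, small_tables):
        _, encounters = parse_tracking_log(*small_tables)
        assert encounters[1].comments is None
        assert encounters[0].comments == "called patient"

    def test_unknown_patient_id_raises_referential_error(self, small_tables):
        demo, enc = small_tables
        enc.loc[0, "patient_id"] = "P999"
        with pytest.raises(ReferentialError, match="P999"):
            parse_tracking_log(demo, enc)

    def test_missing_mandatory_column_names_it(self, small_tables):
        demo, enc = small_tables
        with pytest.raises(SchemaError, match="marital_status"):
            parse_tracking_log(demo.drop(columns=["marital_status"]), enc)
        with pytest.raises(SchemaError, match="sdoh_codes"):
            parse_tracking_log(demo, enc.drop(columns=["sdoh_codes"]))

    def test_write_then_reparse_is_value_identical(self, small_tables, tmp_path):
        patients, encounters = parse_tracking_log(*small_tables)
        write_tracking_log(patients, encounters, tmp_path / "d.csv", tmp_path / "e.csv")
        patients2, encounters2 = parse_tracking_log(tmp_path / "d.csv", tmp_path / "e.csv")
        assert patients == patients2
        assert encounters == encounters2


class TestImpute:
    def test_numeric_missing_takes_mean(self):
        patients = [
            make_patient("P1", age=40.0),
            make_patient("P2", age=50.0),
            make_patient("P3", age=None),
        ]
        out, _, log = impute_missing(patients, [])
        assert out[2].age == 45.0
        assert log.numeric_imputed == {"age": 1}

    def test_categorical_missing_takes_most_common(self):
        patients = [
            make_patient("P1", marital_status="married"),
            make_patient("P2", marital_status="married"),
            make_patient("P3", marital_status="single"),
            make_patient("P4", marital_status=MISSING),
        ]
        out, _, _ = impute_missing(patients, [])
        assert out[3].marital_status == "married"

    def test_mode_tie_breaks_to_lexicographically_smallest(self):
        patients = [
            make_patient("P1", occupation="retired"),
            make_patient("P2", occupation="homemaker"),
            make_patient("P3", occupation=MISSING),
        ]
        out, _, _ = impute_missing(patients, [])
        assert out[2].occupation == "homemaker"

    def test_encounters_missing_codes_or_text_are_dropped(self):
        patients = [make_patient("P1")]
        encounters = [
            make_encounter("P1", ["fear"]),
            make_encounter("P1", None),  # codes never recorded
            make_encounter("P1", ["housing"], comments=None),
        ]
        _, kept, log = impute_missing(patients, encounters)
        assert len(kept) == 1 and kept[0].sdoh_codes == ["fear"]
        assert log.encounters_dropped_no_codes == 1
        assert log.encounters_dropped_no_comments == 1

    def test_all_missing_column_raises_naming_it(self):
        patients = [make_patient("P1", age=None), make_patient("P2", age=None)]
        with pytest.raises(ImputationError, match="age"):
            impute_missing(patients, [])

    def test_never_changes_observed_cells_and_clears_sentinels(self):
        patients = [
            make_patient("P1", occupation="retired", age=61.0),
            make_patient("P2", occupation=MISSING, age=None),
        ]
        out, _, _ = impute_missing(patients, [])
        assert out[0].occupation == "retired" and out[0].age == 61.0
        frame = patients_to_frame(out)
        assert not (frame == MISSING).any().any()


class TestOneHot:
    def test_two_level_column_definition(self):
        table = pd.DataFrame({"c": ["A", "B", "A"]})
        enc, d = one_hot_encode(table, ["c"])
        assert list(enc["c=A"]) == [1, 0, 1]
        assert list(enc["c=B"]) == [0, 1, 0]
        assert d == {"c": ["A", "B"]}

    def test_decode_inverts_encode(self):
        table = pd.DataFrame(
            {"x": ["a", "b", "c", "a"], "n": [1.0, 2.0, 3.0, 4.0], "y": ["u", "v", "u", "u"]}
        )
        enc, d = one_hot_encode(table, ["x", "y"])
        decoded = one_hot_decode(enc, d)
        pd.testing.assert_frame_equal(decoded[table.columns], table)

    def test_level_counts_and_row_segment_sums(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "a": rng.choice(["a1", "a2"], size=20),
                "b": rng.choice(["b1", "b2", "b3"], size=20),
                "c": rng.choice(["c1", "c2", "c3", "c4"], size=20),
            }
        )
        # ensure every level appears
        table.iloc[:9, 0] = ["a1", "a2"] * 4 + ["a1"]
        table.iloc[:3, 1] = ["b1", "b2", "b3"]
        table.iloc[:4, 2] = ["c1", "c2", "c3", "c4"]
        enc, _ = one_hot_encode(table, ["a", "b", "c"])
        assert enc.shape[1] == 2 + 3 + 4
        assert (enc.sum(axis=1) == 3).all()
        for col in ("a", "b", "c"):
            seg = enc[[c for c in enc.columns if c.startswith(f"{col}=")]]
            assert (seg.sum(axis=1) == 1).all()

    def test_unseen_category_error_or_zero_segment(self):
        train = pd.DataFrame({"c": ["A", "B"]})
        test = pd.DataFrame({"c": ["A", "C"]})
        _, d = one_hot_encode(train, ["c"])
        with pytest.raises(ValueError, match="unseen"):
            one_hot_encode(test, ["c"], dictionary=d)
        enc, _ = one_hot_encode(test, ["c"], dictionary=d, unseen="zeros")
        assert list(enc.iloc[1]) == [0, 0]

    def test_residual_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            one_hot_encode(pd.DataFrame({"c": ["A", MISSING]}), ["c"])
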