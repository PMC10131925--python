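"""The six preparation strategies against hand traces and a brute-force oracle."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_encounter, make_patient
from pn_sdoh.strategies import (
    aggregate_encounter_features,
    apply_strategy,
    corpus_frequencies,
    instances_to_frame,
    label_patient_s1,
    salient_sdoh,
)
from pn_sdoh.taxonomy import LANGUAGE_CODE, default_taxonomy


class TestSalient:
    def test_singleton_code_is_returned(self):
        enc = make_encounter("P1", ["fear"])
        assert salient_sdoh(enc, Counter({"fear": 1, "housing": 99})) == "fear"

    def test_highest_corpus_frequency_wins(self):
        enc = make_encounter("P1", ["fear", "transportation"])
        assert salient_sdoh(enc, Counter({"fear": 40, "transportation": 10})) == "fear"

    def test_frequency_tie_breaks_lexicographically(self):
        enc = make_encounter("P1", ["housing", "fear"])
        assert salient_sdoh(enc, Counter({"fear": 5, "housing": 5})) == "fear"

    def test_empty_code_list_rejected(self):
        with pytest.raises(ValueError):
            salient_sdoh(make_encounter("P1", []), Counter())


class TestS1Labeling:
    def _encounters(self, code_lists):
        return [
            make_encounter("P1", codes, date=f"2014-01-{i + 1:02d}", comments=f"note {i}")
            for i, codes in enumerate(code_lists)
        ]

    def test_first_non_language_encounter_sets_label_and_window(self):
        encs = self._encounters([[LANGUAGE_CODE], [LANGUAGE_CODE], ["transportation"], ["fear"]])
        freq = corpus_frequencies(encs)
        inst = label_patient_s1(make_patient("P1"), encs, freq)
        assert inst.label == "transportation"
        assert inst.encounter_positions == [0, 1, 2]  # trigger included
        assert inst.text == "note 0 note 1 note 2"

    def test_all_language_patient_uses_first_encounter_only(self):
        encs = self._encounters([[LANGUAGE_CODE], [LANGUAGE_CODE]])
        inst = label_patient_s1(make_patient("P1"), encs, corpus_frequencies(encs))
        assert inst.label == LANGUAGE_CODE
        assert inst.encounter_positions == [0]

    def test_single_non_language_encounter(self):
        encs = self._encounters([["fear"]])
        inst = label_patient_s1(make_patient("P1"), encs, corpus_frequencies(encs))
        assert inst.label == "fear" and inst.encounter_positions == [0]

    def test_trigger_exclusion_mode_stops_before_trigger(self):
        encs = self._encounters([[LANGUAGE_CODE], ["fear"]])
        inst = label_patient_s1(
            make_patient("P1"), encs, corpus_frequencies(encs), include_trigger=False
        )
        assert inst.label == "fear" and inst.encounter_positions == [0]


class TestApplyStrategy:
    def test_toy_cohort_instance_counts(self, toy_cohort):
        patients, encounters = toy_cohort
        assert len(apply_strategy(patients, encounters, "s1")) == 3
        assert len(apply_strategy(patients, encounters, "s2")) == 1
        assert len(apply_strategy(patients, encounters, "s3")) == 7
        s5 = apply_strategy(patients, encounters, "s5")
        assert len(s5) == 3
        assert all(i.bundle is None and i.text is None for i in s5)

    def test_language_never_labels_s2_s4_s6(self, toy_cohort):
        patients, encounters = toy_cohort
        for s in ("s2", "s4", "s6"):
            assert all(i.label != LANGUAGE_CODE for i in apply_strategy(patients, encounters, s))

    def test_s5_labels_equal_s1_labels_per_patient(self, toy_cohort):
        patients, encounters = toy_cohort
        s1 = {i.patient_id: i.label for i in apply_strategy(patients, encounters, "s1")}
        s5 = {i.patient_id: i.label for i in apply_strategy(patients, encounters, "s5")}
        assert s1 == s5

    def test_unknown_strategy_rejected(self, toy_cohort):
        with pytest.raises(ValueError, match="unknown strategy"):
            apply_strategy(*toy_cohort, "s7")

    def test_patient_with_no_encounters_excluded_everywhere(self, toy_cohort):
        patients, encounters = toy_cohort
        patients = patients + [make_patient("P4")]
        for s in ("s1", "s3", "s5"):
            assert all(
                i.patient_id != "P4" for i in apply_strategy(patients, encounters, s)
            )

    def test_count_inequalities_and_label_validity(self, bruteforce):
        taxonomy = default_taxonomy()
        rng = np.random.default_rng(5)
        for _ in range(20):
            patients, encounters = bruteforce.random_cohort(rng)
            sizes = {s: len(apply_strategy(patients, encounters, s)) for s in
                     ("s1", "s2", "s3", "s4", "s5", "s6")}
            assert sizes["s2"] <= sizes["s1"]
            assert sizes["s4"] <= sizes["s3"]
            assert sizes["s5"] == sizes["s1"]
            assert sizes["s6"] == sizes["s2"]
            for s in ("s1", "s3"):
                for inst in apply_strategy(patients, encounters, s):
                    assert taxonomy.is_valid(inst.label)
                    assert len(inst.encounter_positions) >= 1


class TestAggregate:
    def test_numeric_fields_average(self):
        encs = [
            make_encounter("P1", ["fear"], action_length=10.0),
            make_encounter("P1", ["fear"], action_length=20.0),
        ]
        assert aggregate_encounter_features(encs)["action_length"] == 15.0

    def test_categorical_fields_take_mode(self):
        encs = [
            make_encounter("P1", ["fear"], channel="phone"),
            make_encounter("P1", ["fear"], channel="phone"),
            make_encounter("P1", ["fear"], channel="in_person"),
        ]
        assert aggregate_encounter_features(encs)["channel"] == "phone"

    def test_single_encounter_is_identity(self):
        enc = make_encounter("P1", ["fear"], comments="only note")
        bundle = aggregate_encounter_features([enc])
        assert bundle["action_length"] == enc.action_length
        assert bundle["channel"] == enc.channel
        assert bundle["comments"] == "only note"


def test_strategy_rules_match_bruteforce_oracle(bruteforce):
    """Equivalence with an independent re-implementation of all six
    strategy rules on 100 random toy cohorts."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        patients, encounters = bruteforce.random_cohort(rng)
        for s in ("s1", "s2", "s3", "s4", "s5", "s6"):
            got = [
                (i.patient_id, i.label, tuple(i.encounter_positions))
                for i in apply_strategy(patients, encounters, s)
            ]
            assert got == bruteforce.strategy(patients, encounters, s), s


def test_instances_to_frame_has_topic_ready_text(toy_cohort):
    patients, encounters = toy_cohort
    table = instances_to_frame(apply_strategy(patients, encounters, "s1"), patients)
    assert {"label", "text", "patient_id", "age"} <= set(table.columns)
    assert "enc_channel" in table.columns
    s5_table = instances_to_frame(apply_strategy(patients, encounters, "s5"), patients)
    assert "enc_channel" not in s5_table.columns
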