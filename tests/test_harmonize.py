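"""Codebook harmonization, intensity binning and travel augmentation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_encounter, make_patient
from pn_sdoh.data_model import one_hot_decode
from pn_sdoh.harmonize import (
    FixtureTravelProvider,
    IntensityBins,
    SyntheticTravelProvider,
    TravelInfo,
    assign_intensity,
    binarize_strings,
    derive_bins,
    harmonize,
    intensity_bin,
    map_sdoh_code,
    paper_bins,
    top_k_labels,
    travel_augment,
)
from pn_sdoh.taxonomy import default_taxonomy


class TestCodeMapping:
    def setup_method(self):
        self.alias = default_taxonomy().alias_map

    def test_specific_code_with_direct_match(self):
        assert map_sdoh_code("transport:distance", self.alias) == "distance_from_facility"

    def test_specific_code_falls_back_to_generic_parent(self):
        assert map_sdoh_code("transport:no_car", self.alias) == "transportation"
        assert map_sdoh_code("support:no_near_family", self.alias) == "social_practical_support"

    def test_unknown_code_maps_to_other(self):
        assert map_sdoh_code("astrology:sign", self.alias) == "other"


class TestTopK:
    def test_frequency_ranking(self):
        codes = ["lang"] * 5 + ["none"] * 3 + ["fear"] * 2 + ["transport"]
        assert top_k_labels(codes) == ["lang", "none", "fear"]

    def test_short_list_padded_by_caller(self):
        assert top_k_labels(["fear", "fear"]) == ["fear"]

    def test_tie_breaks_by_first_occurrence(self):
        assert top_k_labels(["a", "b", "a", "b"]) == ["a", "b"]
        assert top_k_labels(["b", "a", "b", "a"]) == ["b", "a"]

    def test_matches_bruteforce_counter_on_random_lists(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            codes = list(rng.choice(list("abcde"), size=rng.integers(0, 30)))
            got = top_k_labels(codes, k=3)
            # independent recount: frequencies of the selected codes must be
            # the top-3 multiset of all frequencies
            freqs = {c: codes.count(c) for c in set(codes)}
            got_freqs = sorted((freqs[c] for c in got), reverse=True)
            best = sorted(freqs.values(), reverse=True)[:3]
            assert got_freqs == best
            assert len(got) == min(3, len(freqs))


class TestIntensity:
    def test_published_threshold_assignments(self):
        bins = paper_bins()
        assert intensity_bin(2, bins) == "L"
        assert intensity_bin(3, bins) == "M"
        assert intensity_bin(15, bins) == "M"
        assert intensity_bin(16, bins) == "H"
        assert intensity_bin(29, bins) == "H"
        assert intensity_bin(30, bins) == "VH"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            intensity_bin(-1, paper_bins())

    def test_partitions_any_count_vector(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 60, size=500)
        bins = paper_bins()
        labels = [intensity_bin(int(c), bins) for c in counts]
        assert len(labels) == 500
        tallies = pd.Series(labels).value_counts()
        assert tallies.sum() == 500
        assert set(tallies.index) <= {"L", "M", "H", "VH"}

    def test_derived_bins_round_mean_and_sd(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=400)
        z = (z - z.mean()) / z.std(ddof=1)
        counts = 16.94 + 13.06 * z  # exact sample mean/sd by construction
        bins = derive_bins(counts)
        assert bins.thresholds == (4, 17, 30)

    def test_constant_counts_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            derive_bins([5, 5, 5])

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            IntensityBins(thresholds=(5, 5, 9))


def _site_a():
    patients = [
        make_patient("A1", occupation="retired"),
        make_patient("A2", occupation="full_time", age=None),
        make_patient("A3"),  # no encounters
    ]
    encounters = [
        make_encounter("A1", ["language_interpreter"], action_taken="interpretation"),
        make_encounter("A1", ["fear"], action_taken="referral"),
        make_encounter("A1", ["fear"], action_taken="referral"),
        make_encounter("A2", ["housing"], action_taken="referral"),
    ]
    return patients, encounters


def _site_b():
    patients = [make_patient("B1", occupation="full time", site="B")]
    encounters = [
        make_encounter("B1", ["transport:no_car"], comments=None, action_taken="examination"),
        make_encounter("B1", ["none"], comments=None, action_taken="examination"),
    ]
    return patients, encounters


class TestHarmonize:
    def test_site_b_employment_recodes_to_site_a_categories(self):
        unified = harmonize(_site_a(), _site_b())
        assert unified.set_index("patient_id").loc["B1", "employment"] == "full_time"

    def test_patient_without_encounters_excluded(self):
        unified = harmonize(_site_a(), _site_b())
        assert "A3" not in set(unified["patient_id"])

    def test_numeric_missing_replaced_with_mean(self):
        unified = harmonize(_site_a(), _site_b())
        ages = unified.set_index("patient_id")["age"]
        assert ages["A2"] == pytest.approx(ages[["A1", "B1"]].mean())

    def test_schema_identical_across_sites_and_codes_unified(self):
        unified = harmonize(_site_a(), _site_b())
        taxonomy = default_taxonomy()
        assert unified.isna().sum().sum() == 0
        for col in ("barrier_1", "barrier_2", "barrier_3"):
            for v in unified[col]:
                assert v == "" or taxonomy.is_valid(v)
        # B1's codes were mapped into the site-A taxonomy
        b1 = unified.set_index("patient_id").loc["B1"]
        assert b1["barrier_1"] in ("transportation", "none")

    def test_barriers_listed_by_descending_frequency(self):
        unified = harmonize(_site_a(), _site_b()).set_index("patient_id")
        assert unified.loc["A1", "barrier_1"] == "fear"  # 2 occurrences
        assert unified.loc["A1", "barrier_2"] == "language_interpreter"

    def test_foreign_language_value_converted_to_none(self):
        patients, encounters = _site_a()
        patients[0].marital_status = "已婚"
        unified = harmonize((patients, encounters), _site_b())
        assert unified.set_index("patient_id").loc["A1", "marital_status"] == "none"


class TestTravel:
    def test_fixture_provider_returns_tuple_verbatim(self):
        provider = FixtureTravelProvider(
            {"60616": TravelInfo("H1", 3.2, 12.0, 34.0)}
        )
        records = pd.DataFrame({"zip_code": ["60616"], "patient_id": ["A1"]})
        out = travel_augment(records, provider)
        assert out.loc[0, "nearest_hospital_id"] == "H1"
        assert out.loc[0, "distance_km"] == 3.2
        assert out.loc[0, "drive_minutes"] == 12.0
        assert out.loc[0, "transit_minutes"] == 34.0

    def test_absent_transit_imputed_with_mean(self):
        provider = FixtureTravelProvider(
            {
                "z1": TravelInfo("H1", 1.0, 5.0, 30.0),
                "z2": TravelInfo("H1", 1.0, 5.0, None),
                "z3": TravelInfo("H1", 1.0, 5.0, 50.0),
            }
        )
        records = pd.DataFrame({"zip_code": ["z1", "z2", "z3"]})
        out = travel_augment(records, provider)
        assert out.loc[1, "transit_minutes"] == 40.0

    def test_all_transit_absent_raises_with_guidance(self):
        provider = FixtureTravelProvider({"z1": TravelInfo("H1", 1.0, 5.0, None)})
        with pytest.raises(ValueError, match="default"):
            travel_augment(pd.DataFrame({"zip_code": ["z1"]}), provider)

    def test_synthetic_provider_deterministic_per_zip(self):
        provider = SyntheticTravelProvider()
        assert provider.lookup("60616") == provider.lookup("60616")
        info = provider.lookup("60608")
        assert info.distance_km > 0 and info.drive_minutes > 0


class TestBinarize:
    def test_targets_limited_to_top_three(self):
        unified = harmonize(_site_a(), _site_b())
        unified = assign_intensity(unified, paper_bins())
        unified = travel_augment(unified, SyntheticTravelProvider())
        X, dictionary, Y = binarize_strings(unified)
        assert (Y.sum(axis=1) <= 3).all()
        assert set(Y.to_numpy().ravel()) <= {0, 1}

    def test_feature_matrix_is_binary_plus_numeric_and_decodable(self):
        unified = harmonize(_site_a(), _site_b())
        unified = assign_intensity(unified, paper_bins())
        unified = travel_augment(unified, SyntheticTravelProvider())
        X, dictionary, _ = binarize_strings(unified)
        decoded = one_hot_decode(X, dictionary)
        for col in dictionary:
            assert list(decoded[col]) == list(unified[col].astype(str))


def test_taxonomy_loads_from_editable_yaml(tmp_path):
    from pn_sdoh.taxonomy import taxonomy_from_yaml

    path = tmp_path / "codebook.yaml"
    path.write_text(
        "codes: [fear, housing]\nalias_map:\n  miedo: fear\n  vivienda: housing\n"
    )
    taxonomy = taxonomy_from_yaml(path)
    assert taxonomy.codes == ("fear", "housing")
    assert map_sdoh_code("miedo:renta", taxonomy.alias_map) == "fear"
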