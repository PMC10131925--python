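"""Shared fixtures: hand-built toy cohorts, random-cohort factories, and an
independent brute-force re-implementation of the preparation-strategy rules
used as an oracle against the library implementation."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from pn_sdoh.data_model import Encounter, Patient
from pn_sdoh.taxonomy import LANGUAGE_CODE


def make_patient(pid: str, **kw) -> Patient:
    defaults = dict(
        age=50.0,
        occupation="retired",
        marital_status="married",
        education_level="primary",
        year_arrived_us=1990.0,
        english_level="poor",
        origin="china",
        zip_code="60616",
        household_size=3.0,
        born_in_us="no",
        income_range="lt_10k",
    )
    defaults.update(kw)
    return Patient(patient_id=pid, **defaults)


def make_encounter(pid: str, codes, date="2014-01-01", comments="note text", **kw) -> Encounter:
    defaults = dict(
        preferred_language="cantonese",
        all_languages="cantonese",
        service_type="screening",
        channel="phone",
        action_length=20.0,
        action_taken="referral",
    )
    defaults.update(kw)
    return Encounter(
        patient_id=pid,
        date=date,
        comments=comments,
        sdoh_codes=list(codes) if codes is not None else None,
        **defaults,
    )


@pytest.fixture
def toy_cohort():
    """3 patients, 7 encounters, 2 language-only patients.

    P1's first non-language encounter is its third (transportation), so S1
    labels P1 transportation over the window of encounters 1-3.
    """
    patients = [make_patient("P1"), make_patient("P2"), make_patient("P3")]
    encounters = [
        make_encounter("P1", [LANGUAGE_CODE], date="2014-01-01"),
        make_encounter("P1", [LANGUAGE_CODE], date="2014-01-08"),
        make_encounter("P1", ["transportation"], date="2014-01-15"),
        make_encounter("P1", ["fear"], date="2014-01-22"),
        make_encounter("P2", [LANGUAGE_CODE], date="2014-02-01"),
        make_encounter("P3", [LANGUAGE_CODE], date="2014-02-02"),
        make_encounter("P3", [LANGUAGE_CODE], date="2014-02-09"),
    ]
    return patients, encounters


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the strategy rules


def _bf_frequencies(encounters):
    freq = {}
    for e in encounters:
        for c in e.sdoh_codes or []:
            freq[c] = freq.get(c, 0) + 1
    return freq


def _bf_salient(codes, freq):
    best = None
    for c in sorted(codes):  # lexicographic scan => smallest wins ties
        if best is None or freq.get(c, 0) > freq.get(best, 0):
            best = c
    return best


def _bf_order(encounters, idxs):
    return sorted(idxs, key=lambda i: (encounters[i].date, i))


def _bf_strategy(patients, encounters, strategy):
    """Returns [(patient_id, label, window positions)] per the stated rules."""
    freq = _bf_frequencies(encounters)
    out = []
    for p in patients:
        idxs = _bf_order(
            encounters, [i for i, e in enumerate(encounters) if e.patient_id == p.patient_id]
        )
        if not idxs:
            continue
        if strategy in ("s1", "s2", "s5", "s6"):
            label, window = None, None
            for j, i in enumerate(idxs):
                s = _bf_salient(encounters[i].sdoh_codes, freq)
                if s != LANGUAGE_CODE:
                    label, window = s, idxs[: j + 1]
                    break
            if label is None:
                label, window = LANGUAGE_CODE, [idxs[0]]
            if strategy in ("s2", "s6") and label == LANGUAGE_CODE:
                continue
            out.append((p.patient_id, label, tuple(window)))
        else:  # s3 / s4
            for i in idxs:
                s = _bf_salient(encounters[i].sdoh_codes, freq)
                if strategy == "s4" and s == LANGUAGE_CODE:
                    continue
                out.append((p.patient_id, s, (i,)))
    return out


def _random_toy_cohort(rng: np.random.Generator):
    """A random cohort of <= 10 patients with arbitrary code lists."""
    pool = [LANGUAGE_CODE, "fear", "transportation", "housing", "none"]
    n = int(rng.integers(1, 11))
    patients = [make_patient(f"R{i}") for i in range(n)]
    encounters = []
    for p in patients:
        for k in range(int(rng.integers(0, 7))):
            n_codes = int(rng.integers(1, 4))
            codes = list(rng.choice(pool, size=n_codes, replace=False))
            date = f"2014-0{int(rng.integers(1, 10))}-{int(rng.integers(1, 29)):02d}"
            encounters.append(make_encounter(p.patient_id, codes, date=date))
    return patients, encounters


@pytest.fixture(scope="session")
def bruteforce():
    return SimpleNamespace(
        frequencies=_bf_frequencies,
        salient=_bf_salient,
        strategy=_bf_strategy,
        random_cohort=_random_toy_cohort,
    )
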