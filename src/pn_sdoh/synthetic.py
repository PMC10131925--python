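"""Synthetic two-site patient-navigation tracking logs with known ground truth.

The generator emulates the structure of navigation logs from a breast/
cervical-cancer screening program serving a limited-English immigrant
cohort: overdispersed per-patient encounter counts (negative binomial
matched to a printed mean of 16.94 and SD of 13.06), heavy class imbalance
with language/interpreter as the dominant barrier, short bag-of-words
navigator notes driven by latent topics, and configurable log-odds links
from demographics and note topics to per-encounter SDoH assignment.  A
second site ("B") mimics an incompatible codebook: two-level
generic:specific SDoH codes, a 3-level employment variable, exactly one
SDoH plus an action per encounter, and no note text.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

from .data_model import MISSING, Encounter, Patient
from .taxonomy import NONE_CODE, SDoHTaxonomy, default_taxonomy


class ConfigError(ValueError):
    """Degenerate or invalid generator configuration."""


# -- default building blocks -------------------------------------------------

_OCCUPATIONS = ("full_time", "part_time", "unemployed", "retired", "homemaker", "student")
_OCC_P = (0.25, 0.15, 0.20, 0.20, 0.15, 0.05)
_MARITAL = ("married", "single", "widowed", "divorced")
_MARITAL_P = (0.60, 0.15, 0.15, 0.10)
_EDUCATION = ("no_formal", "primary", "secondary", "college")
_EDU_P = (0.15, 0.35, 0.35, 0.15)
_ENGLISH = ("none", "poor", "fair", "good")
_ENGLISH_P = (0.35, 0.35, 0.20, 0.10)
_ORIGIN = ("china", "hong_kong", "taiwan", "vietnam", "us")
_ORIGIN_P = (0.60, 0.15, 0.10, 0.10, 0.05)
_INCOME = ("lt_10k", "10k_20k", "20k_30k", "30k_50k", "gt_50k")
_INCOME_P = (0.30, 0.30, 0.20, 0.15, 0.05)
_ZIPS = ("60605", "60608", "60609", "60616", "60617", "60623", "60628", "60632")
_LANGS = ("cantonese", "mandarin", "toishanese", "english")
_LANGS_P = (0.40, 0.25, 0.25, 0.10)
_SERVICES = ("screening", "follow_up", "education", "scheduling")
_CHANNELS = ("phone", "in_person", "mail")
_CHANNELS_P = (0.55, 0.35, 0.10)
_ACTIONS = (
    "interpretation",
    "appointment_scheduling",
    "referral",
    "education_materials",
    "paperwork_assist",
    "emotional_support",
)
_ACTIONS_P = (0.30, 0.25, 0.15, 0.12, 0.10, 0.08)

#: Default per-topic vocabularies for navigator-note generation.
DEFAULT_TOPICS: tuple[tuple[str, ...], ...] = (
    ("appointment", "schedule", "call", "clinic", "reminder", "confirm", "visit", "reschedule"),
    ("bus", "ride", "drive", "car", "travel", "far", "transit", "pickup"),
    ("insurance", "coverage", "cost", "pay", "bill", "medicaid", "application", "enroll"),
    ("worried", "fear", "anxious", "reassure", "family", "support", "talk", "comfort"),
)

#: Default per-encounter SDoH base rates (multi-label Bernoulli).  The
#: language/interpreter rate dominates, mirroring the pervasive language
#: barrier in navigation logs for limited-English cohorts.
DEFAULT_BASE_RATES: dict[str, float] = {
    "language_interpreter": 0.60,
    "social_practical_support": 0.10,
    "insurance_uninsured_underinsured": 0.08,
    "fear": 0.06,
    "financial_problems": 0.05,
    "transportation": 0.05,
    "perceptions_beliefs_about_treatment": 0.04,
    "system_problems_scheduling": 0.04,
    "literacy": 0.03,
    "housing": 0.02,
    "family_community_issues": 0.02,
    "other": 0.02,
}

#: Planted demographic links: code -> [(column, value, log-odds shift)].
DEFAULT_DEMO_SIGNAL: dict[str, list[tuple[str, str, float]]] = {
    "language_interpreter": [("english_level", "none", 1.2)],
    "insurance_uninsured_underinsured": [
        ("income_range", "lt_10k", 1.2),
        ("income_range", "10k_20k", 0.6),
    ],
    "financial_problems": [("occupation", "unemployed", 1.2)],
    "social_practical_support": [("marital_status", "widowed", 1.2)],
    "literacy": [("education_level", "no_formal", 1.0)],
}

#: Planted topic links: code -> {topic index: log-odds shift at full weight}.
DEFAULT_TOPIC_SIGNAL: dict[str, dict[int, float]] = {
    "system_problems_scheduling": {0: 1.5},
    "transportation": {1: 2.0},
    "insurance_uninsured_underinsured": {2: 1.5},
    "fear": {3: 2.0},
}

#: Default site-B categorical probabilities over its own codebook (exactly
#: one code per encounter; the wildcard "none" dominates, as in logs where
#: navigators record "none" once a barrier has already been determined).
DEFAULT_SITE_B_RATES: dict[str, float] = {
    "none": 0.38,
    "language:interpreter_needed": 0.16,
    "language": 0.06,
    "casemgmt": 0.08,
    "casemgmt:referral": 0.04,
    "transport:no_car": 0.05,
    "transport:distance": 0.03,
    "finance:copay": 0.05,
    "insurance:lapsed": 0.05,
    "support:no_near_family": 0.04,
    "family:childcare": 0.03,
    "fear:diagnosis": 0.02,
    "beliefs:screening": 0.01,
}


@dataclass
class CohortConfig:
    """Generator settings; the defaults are the study conditions.

    ``signal_strength`` scales every planted log-odds link at once; zero
    removes all structure so empirical code frequencies equal the base
    rates in expectation.
    """

    n_patients: int = 330
    n_patients_b: int | None = None  # site-B cohort size (defaults to n_patients)
    encounter_mean: float = 16.94
    encounter_sd: float = 13.06
    sdoh_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    signal_strength: float = 1.0
    demo_signal: dict[str, list[tuple[str, str, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_DEMO_SIGNAL.items()}
    )
    topic_signal: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TOPIC_SIGNAL.items()}
    )
    topic_spec: tuple[tuple[str, ...], ...] = DEFAULT_TOPICS
    doc_topic_alpha: float = 0.3
    note_length_mean: float = 12.0
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.04,
            "year_arrived_us": 0.06,
            "household_size": 0.04,
            "occupation": 0.04,
            "marital_status": 0.03,
            "education_level": 0.05,
            "english_level": 0.03,
            "origin": 0.02,
            "zip_code": 0.02,
            "born_in_us": 0.02,
            "income_range": 0.08,
            "action_length": 0.04,
            "comments": 0.08,
            "sdoh_codes": 0.05,
        }
    )
    site_b_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_B_RATES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        if self.encounter_sd**2 <= self.encounter_mean:
            raise ConfigError(
                "encounter counts are negative-binomial; variance must exceed the mean"
            )
        for code, p in self.sdoh_base_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"base rate for {code!r} outside [0, 1]")
        for col, p in self.missingness_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"missingness rate for {col!r} outside [0, 1]")
        if self.note_length_mean <= 0:
            raise ConfigError("note_length_mean must be positive")


@dataclass
class GroundTruth:
    """Generating truth for one synthetic cohort."""

    per_patient_true: dict[str, set[str]]
    coefficients: dict[str, object]
    per_encounter_topics: list[tuple[str, np.ndarray]]


def _nb_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return float(np.log(p / (1 - p)))


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _sample_patient(rng: np.random.Generator, pid: str, site: str = "A") -> Patient:
    origin = rng.choice(_ORIGIN, p=_ORIGIN_P)
    born_in_us = "yes" if origin == "us" else ("yes" if rng.random() < 0.05 else "no")
    return Patient(
        patient_id=pid,
        age=float(np.clip(rng.normal(55, 12), 21, 90).round(0)),
        occupation=str(rng.choice(_OCCUPATIONS, p=_OCC_P)),
        marital_status=str(rng.choice(_MARITAL, p=_MARITAL_P)),
        education_level=str(rng.choice(_EDUCATION, p=_EDU_P)),
        year_arrived_us=float(rng.integers(1975, 2016)),
        english_level=str(rng.choice(_ENGLISH, p=_ENGLISH_P)),
        origin=str(origin),
        zip_code=str(rng.choice(_ZIPS)),
        household_size=float(rng.poisson(2.5) + 1),
        born_in_us=born_in_us,
        income_range=str(rng.choice(_INCOME, p=_INCOME_P)),
        site=site,
    )


def _demo_shift(cfg: CohortConfig, patient: Patient, code: str) -> float:
    shift = 0.0
    for column, value, coef in cfg.demo_signal.get(code, ()):
        if str(getattr(patient, column)) == value:
            shift += coef
    return shift


def _note(rng: np.random.Generator, cfg: CohortConfig, theta: np.ndarray) -> str:
    length = max(1, int(rng.poisson(cfg.note_length_mean)))
    topics = rng.choice(len(cfg.topic_spec), size=length, p=theta)
    words = [cfg.topic_spec[t][rng.integers(len(cfg.topic_spec[t]))] for t in topics]
    return " ".join(words)


def generate_cohort(
    config: CohortConfig | None = None,
    taxonomy: SDoHTaxonomy | None = None,
) -> tuple[list[Patient], list[Encounter], GroundTruth]:
    """Generate a site-A cohort: demographics, encounters, generating truth.

    Per encounter, each SDoH category fires as an independent Bernoulli
    whose log-odds are the base-rate logit plus ``signal_strength`` times
    the patient's demographic shifts and the encounter's topic-mixture
    shifts.  An encounter where nothing fires records the wildcard "none".
    Missingness is injected last, after the truth is recorded.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(cfg.seed)
    r, p = _nb_params(cfg.encounter_mean, cfg.encounter_sd)

    code_order = sorted(cfg.sdoh_base_rates)
    patients: list[Patient] = []
    encounters: list[Encounter] = []
    truth_sets: dict[str, set[str]] = {}
    topic_log: list[tuple[str, np.ndarray]] = []

    for i in range(cfg.n_patients):
        pid = f"A{i + 1:04d}"
        patient = _sample_patient(rng, pid, site="A")
        patients.append(patient)
        n_enc = int(rng.negative_binomial(r, p))
        truth_sets[pid] = set()
        day = rng.integers(0, 60)
        for _ in range(n_enc):
            theta = rng.dirichlet(np.full(len(cfg.topic_spec), cfg.doc_topic_alpha))
            topic_log.append((pid, theta))
            codes: list[str] = []
            for code in code_order:
                logit = _logit(cfg.sdoh_base_rates[code])
                logit += cfg.signal_strength * _demo_shift(cfg, patient, code)
                for t_idx, coef in cfg.topic_signal.get(code, {}).items():
                    logit += cfg.signal_strength * coef * float(theta[t_idx])
                if rng.random() < _sigmoid(logit):
                    codes.append(code)
            if not codes:
                codes = [NONE_CODE]
            truth_sets[pid].update(c for c in codes if c != NONE_CODE)
            date = (
                pd.Timestamp("2014-01-01") + pd.Timedelta(days=int(day))
            ).strftime("%Y-%m-%d")
            day += rng.integers(3, 45)
            encounters.append(
                Encounter(
                    patient_id=pid,
                    date=date,
                    preferred_language=str(rng.choice(_LANGS, p=_LANGS_P)),
                    all_languages=str(rng.choice(_LANGS, p=_LANGS_P)),
                    service_type=str(rng.choice(_SERVICES)),
                    channel=str(rng.choice(_CHANNELS, p=_CHANNELS_P)),
                    action_length=float(np.round(rng.lognormal(3.0, 0.5), 1)),
                    action_taken=str(rng.choice(_ACTIONS, p=_ACTIONS_P)),
                    comments=_note(rng, cfg, theta),
                    sdoh_codes=codes,
                )
            )

    _inject_missingness(rng, cfg, patients, encounters)
    truth = GroundTruth(
        per_patient_true=truth_sets,
        coefficients={
            "base_rates": dict(cfg.sdoh_base_rates),
            "signal_strength": cfg.signal_strength,
            "demo_signal": {k: list(v) for k, v in cfg.demo_signal.items()},
            "topic_signal": {k: dict(v) for k, v in cfg.topic_signal.items()},
        },
        per_encounter_topics=topic_log,
    )
    return patients, encounters, truth


def _inject_missingness(
    rng: np.random.Generator,
    cfg: CohortConfig,
    patients: list[Patient],
    encounters: list[Encounter],
) -> None:
    numeric_patient = {"age", "year_arrived_us", "household_size"}
    for p_rec in patients:
        for col, rate in cfg.missingness_rates.items():
            if not hasattr(p_rec, col) or rate <= 0:
                continue
            if rng.random() < rate:
                setattr(p_rec, col, None if col in numeric_patient else MISSING)
    for e in encounters:
        for col in ("action_length", "comments", "sdoh_codes"):
            rate = cfg.missingness_rates.get(col, 0.0)
            if rate > 0 and rng.random() < rate:
                setattr(e, col, None)


# -- site B ------------------------------------------------------------------

_EMPLOYMENT_B = ("unemployed", "part-time", "full time")
_EMPLOYMENT_B_P = (0.35, 0.25, 0.40)
_ACTIONS_B = ("examination", "referral", "follow_up_call", "document_help")


def generate_site_b(
    config: CohortConfig | None = None,
) -> tuple[list[Patient], list[Encounter]]:
    """Generate a site-B cohort in the DuPage-style codebook.

    Differences from site A: employment has only 3 levels, SDoH codes are
    generic/specific pairs with exactly one code per encounter plus an
    action, and the log has no note text.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    r, p = _nb_params(cfg.encounter_mean, cfg.encounter_sd)

    codes_b = sorted(cfg.site_b_rates)
    probs = np.array([cfg.site_b_rates[c] for c in codes_b], dtype=float)
    if probs.sum() <= 0:
        raise ConfigError("site_b_rates must have positive mass")
    probs = probs / probs.sum()

    n_b = cfg.n_patients_b if cfg.n_patients_b is not None else cfg.n_patients
    patients: list[Patient] = []
    encounters: list[Encounter] = []
    for i in range(n_b):
        pid = f"B{i + 1:04d}"
        patient = _sample_patient(rng, pid, site="B")
        patient.occupation = str(rng.choice(_EMPLOYMENT_B, p=_EMPLOYMENT_B_P))
        patient.origin = str(rng.choice(("mexico", "us", "poland", "india", "other")))
        patients.append(patient)
        n_enc = int(rng.negative_binomial(r, p))
        day = rng.integers(0, 60)
        for _ in range(n_enc):
            date = (
                pd.Timestamp("2009-06-01") + pd.Timedelta(days=int(day))
            ).strftime("%Y-%m-%d")
            day += rng.integers(3, 45)
            encounters.append(
                Encounter(
                    patient_id=pid,
                    date=date,
                    preferred_language=str(rng.choice(("spanish", "english", "polish", "other"))),
                    all_languages=str(rng.choice(("spanish", "english", "polish", "other"))),
                    service_type=str(rng.choice(_SERVICES)),
                    channel=str(rng.choice(_CHANNELS, p=_CHANNELS_P)),
                    action_length=float(np.round(rng.lognormal(3.0, 0.5), 1)),
                    action_taken=str(rng.choice(_ACTIONS_B)),
                    comments=None,
                    sdoh_codes=[str(rng.choice(codes_b, p=probs))],
                )
            )
    return patients, encounters


def ground_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Tabulate the generating truth for recovery tests."""
    rows = [
        {
            "patient_id": pid,
            "true_codes": ";".join(sorted(codes)),
            "n_codes": len(codes),
        }
        for pid, codes in sorted(truth.per_patient_true.items())
    ]
    return pd.DataFrame(rows, columns=["patient_id", "true_codes", "n_codes"])


def label_frequencies(truth: GroundTruth) -> pd.Series:
    """Per-code patient counts in the generating truth."""
    counts: dict[str, int] = {}
    for codes in truth.per_patient_true.values():
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
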