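"""The six preparation strategies that turn tracking logs into labeled instances.

Navigation logs are longitudinal and multi-label per encounter, while the
single-label experiment needs one (features, SDoH) pair per data point.
Strategies S1–S4 use encounter data, S5–S6 demographics only; S2, S4 and
S6 additionally exclude the dominant language/interpreter label:

* S1 — each patient is a data point.  Each encounter is reduced to its
  most *salient* SDoH (the code with the highest corpus-wide frequency);
  encounters are scanned in date order up to and including the first whose
  salient SDoH is not language/interpreter, that SDoH becomes the label
  and the scanned window is aggregated into the features.  If every
  encounter is language/interpreter, the label is language/interpreter and
  only the first encounter contributes features.
* S2 — S1 minus instances labeled language/interpreter.
* S3 — each encounter is a data point labeled with its own salient SDoH;
  demographics repeat across a patient's encounters.
* S4 — S3 minus language-labeled instances.
* S5 — S1 labels with all encounter-derived features removed.
* S6 — S2 labels with all encounter-derived features removed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import (
    ENCOUNTER_CATEGORICAL,
    PATIENT_CATEGORICAL,
    PATIENT_NUMERIC,
    Encounter,
    Patient,
)
from .taxonomy import LANGUAGE_CODE

logger = logging.getLogger(__name__)

STRATEGIES = ("s1", "s2", "s3", "s4", "s5", "s6")
#: Strategies whose features include encounter data (and hence note topics).
NOTE_STRATEGIES = ("s1", "s2", "s3", "s4")
DEMOGRAPHIC_STRATEGIES = ("s5", "s6")


@dataclass
class LabeledInstance:
    """One training row: provenance refs, one SDoH label, feature bundles."""

    instance_id: str
    patient_id: str
    label: str
    strategy: str
    encounter_positions: list[int]  # global positions of contributing encounters
    bundle: dict | None  # aggregated encounter features (None for S5/S6)
    text: str | None  # aggregated note text (None for S5/S6)


def corpus_frequencies(encounters: Iterable[Encounter]) -> Counter:
    """Corpus-wide occurrence count of every SDoH code."""
    freq: Counter = Counter()
    for e in encounters:
        for c in e.sdoh_codes or ():
            freq[c] += 1
    return freq


def salient_sdoh(encounter: Encounter, frequencies: Counter) -> str:
    """The encounter's code with the highest corpus-wide frequency.

    Ties break to the lexicographically smallest code, keeping the
    reduction deterministic and seed-free.
    """
    codes = encounter.sdoh_codes or []
    if not codes:
        raise ValueError("encounter has no SDoH codes; drop it upstream")
    return min(codes, key=lambda c: (-frequencies[c], c))


def order_encounters(
    encounters: Sequence[Encounter], positions: Sequence[int]
) -> list[int]:
    """Longitudinal order: by recorded date, ties by file order."""
    return sorted(positions, key=lambda i: (encounters[i].date, i))


def aggregate_encounter_features(encounters: Sequence[Encounter]) -> dict:
    """Collapse a window of encounters into one feature bundle.

    Numeric fields average; categorical fields take the most common value
    (lexicographically smallest on ties); note texts concatenate in order
    into a single document for topic inference.
    """
    if not encounters:
        raise ValueError("cannot aggregate an empty encounter window")
    bundle: dict = {}
    lengths = [e.action_length for e in encounters if e.action_length is not None]
    bundle["action_length"] = sum(lengths) / len(lengths) if lengths else None
    for col in ENCOUNTER_CATEGORICAL:
        counts = Counter(str(getattr(e, col)) for e in encounters)
        top = max(counts.values())
        bundle[col] = min(v for v, c in counts.items() if c == top)
    bundle["comments"] = " ".join(e.comments for e in encounters if e.comments)
    return bundle


def label_patient_s1(
    patient: Patient,
    encounters: Sequence[Encounter],
    frequencies: Counter,
    *,
    positions: Sequence[int] | None = None,
    include_trigger: bool = True,
) -> LabeledInstance:
    """Apply the S1 rule to one patient's retained encounters.

    ``include_trigger`` keeps the first non-language encounter inside the
    aggregation window (default; its note presumably discusses the labeled
    barrier).  The alternative reading of "leading up to" stops the window
    just before it.
    """
    if not encounters:
        raise ValueError(f"patient {patient.patient_id} has no retained encounters")
    positions = list(positions) if positions is not None else list(range(len(encounters)))
    order = order_encounters(encounters, range(len(encounters)))
    salients = [salient_sdoh(encounters[i], frequencies) for i in order]

    trigger = next((j for j, s in enumerate(salients) if s != LANGUAGE_CODE), None)
    if trigger is None:
        label = LANGUAGE_CODE
        window = [order[0]]
    else:
        label = salients[trigger]
        if include_trigger:
            window = order[: trigger + 1]
        else:
            window = order[:trigger] if trigger > 0 else [order[trigger]]
    window_encounters = [encounters[i] for i in window]
    return LabeledInstance(
        instance_id=f"s1-{patient.patient_id}",
        patient_id=patient.patient_id,
        label=label,
        strategy="s1",
        encounter_positions=[positions[i] for i in window],
        bundle=aggregate_encounter_features(window_encounters),
        text=aggregate_encounter_features(window_encounters)["comments"],
    )


def _group_by_patient(
    patients: Sequence[Patient], encounters: Sequence[Encounter]
) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {p.patient_id: [] for p in patients}
    for i, e in enumerate(encounters):
        if e.patient_id in groups:
            groups[e.patient_id].append(i)
    return groups


def apply_strategy(
    patients: Sequence[Patient],
    encounters: Sequence[Encounter],
    strategy: str,
    *,
    include_trigger: bool = True,
) -> list[LabeledInstance]:
    """Produce the labeled instances of one preparation strategy.

    Patients with zero retained encounters are excluded from every
    strategy (with a logged reason).
    """
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    freq = corpus_frequencies(encounters)
    groups = _group_by_patient(patients, encounters)
    by_id = {p.patient_id: p for p in patients}

    skipped = [pid for pid, idxs in groups.items() if not idxs]
    if skipped:
        logger.info("skipping %d patients with zero retained encounters", len(skipped))

    if strategy in ("s1", "s2", "s5", "s6"):
        base: list[LabeledInstance] = []
        for p in patients:
            idxs = groups[p.patient_id]
            if not idxs:
                continue
            inst = label_patient_s1(
                p,
                [encounters[i] for i in idxs],
                freq,
                positions=idxs,
                include_trigger=include_trigger,
            )
            base.append(inst)
        if strategy in ("s2", "s6"):
            base = [i for i in base if i.label != LANGUAGE_CODE]
        if strategy in ("s5", "s6"):
            base = [
                LabeledInstance(
                    instance_id=f"{strategy}-{i.patient_id}",
                    patient_id=i.patient_id,
                    label=i.label,
                    strategy=strategy,
                    encounter_positions=list(i.encounter_positions),
                    bundle=None,
                    text=None,
                )
                for i in base
            ]
        else:
            for i in base:
                i.strategy = strategy
                i.instance_id = f"{strategy}-{i.patient_id}"
        return base

    # S3 / S4: each retained encounter is a data point
    instances: list[LabeledInstance] = []
    for p in patients:
        idxs = order_encounters(encounters, groups[p.patient_id])
        for k, i in enumerate(idxs):
            e = encounters[i]
            label = salient_sdoh(e, freq)
            instances.append(
                LabeledInstance(
                    instance_id=f"{strategy}-{p.patient_id}-{k:03d}",
                    patient_id=p.patient_id,
                    label=label,
                    strategy=strategy,
                    encounter_positions=[i],
                    bundle=aggregate_encounter_features([e]),
                    text=e.comments or "",
                )
            )
    if strategy == "s4":
        instances = [i for i in instances if i.label != LANGUAGE_CODE]
    return instances


def instances_to_frame(
    instances: Sequence[LabeledInstance], patients: Sequence[Patient]
) -> pd.DataFrame:
    """Assemble a feature/label table (plus a raw ``text`` column).

    Demographic columns always appear; encounter-bundle columns appear only
    for strategies that use encounter data.  The ``label``, ``patient_id``
    and ``text`` columns are carried for downstream CV and topic fitting.
    """
    by_id = {p.patient_id: p for p in patients}
    rows = []
    for inst in instances:
        p = by_id[inst.patient_id]
        row: dict = {"instance_id": inst.instance_id, "patient_id": inst.patient_id}
        for col in PATIENT_NUMERIC:
            row[col] = getattr(p, col)
        for col in PATIENT_CATEGORICAL:
            row[col] = str(getattr(p, col))
        if inst.bundle is not None:
            row["action_length"] = inst.bundle["action_length"]
            for col in ENCOUNTER_CATEGORICAL:
                row[f"enc_{col}"] = inst.bundle[col]
        row["text"] = inst.text if inst.text is not None else ""
        row["label"] = inst.label
        rows.append(row)
    return pd.DataFrame(rows)
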