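"""Schemas, readers/writers, imputation and encoding for PN tracking logs.

A tracking log is a pair of CSV tables: one demographics row per patient
and one row per navigation encounter.  Missing cells are normalized to a
single reserved sentinel on parse; imputation replaces numeric blanks with
the column mean and categorical blanks with the most common observed value
(lexicographically smallest on ties), while encounters missing their free
text or their SDoH codes are dropped from strategy inputs rather than
imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import SDoHTaxonomy, default_taxonomy

logger = logging.getLogger(__name__)

#: Reserved sentinel for a missing categorical cell; distinct from every
#: codebook value.  Empty strings and common NA spellings normalize to it.
MISSING = "__missing__"

#: Cell spellings normalized to the missing sentinel on parse.
NA_TOKENS = frozenset({"", "na", "n/a", "nan", "null", MISSING})

#: Separator for multi-valued SDoH code cells.
CODE_SEP = ";"


class SchemaError(ValueError):
    """A mandatory column is absent from an input table."""


class ReferentialError(ValueError):
    """An encounter references a patient id absent from demographics."""


class ImputationError(ValueError):
    """A column to impute contains no observed values."""


@dataclass
class Patient:
    """One study participant's demographic record."""

    patient_id: str
    age: float | None = None
    occupation: str = MISSING
    marital_status: str = MISSING
    education_level: str = MISSING
    year_arrived_us: float | None = None
    english_level: str = MISSING
    origin: str = MISSING
    zip_code: str = MISSING
    household_size: float | None = None
    born_in_us: str = MISSING
    income_range: str = MISSING
    site: str = "A"


@dataclass
class Encounter:
    """One navigation interaction between a navigator and a patient."""

    patient_id: str
    date: str = MISSING
    preferred_language: str = MISSING
    all_languages: str = MISSING
    service_type: str = MISSING
    channel: str = MISSING
    action_length: float | None = None
    action_taken: str = MISSING
    comments: str | None = None  # None = not recorded
    sdoh_codes: list[str] | None = None  # None = not recorded

    def has_comments(self) -> bool:
        return self.comments is not None

    def has_codes(self) -> bool:
        return self.sdoh_codes is not None and len(self.sdoh_codes) > 0


PATIENT_NUMERIC = ("age", "year_arrived_us", "household_size")
PATIENT_CATEGORICAL = (
    "occupation",
    "marital_status",
    "education_level",
    "english_level",
    "origin",
    "zip_code",
    "born_in_us",
    "income_range",
)
ENCOUNTER_NUMERIC = ("action_length",)
ENCOUNTER_CATEGORICAL = (
    "preferred_language",
    "all_languages",
    "service_type",
    "channel",
    "action_taken",
)

DEMOGRAPHICS_COLUMNS = tuple(f.name for f in fields(Patient))
ENCOUNTER_COLUMNS = tuple(f.name for f in fields(Encounter))
#: Columns a site may legitimately omit (site B records no notes and may
#: omit encounter dates).
OPTIONAL_ENCOUNTER_COLUMNS = ("comments", "date")


def _norm_cell(value: object) -> str:
    s = str(value).strip()
    return MISSING if s.lower() in NA_TOKENS else s


def _norm_numeric(value: object) -> float | None:
    s = str(value).strip()
    if s.lower() in NA_TOKENS:
        return None
    return float(s)


def _read_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source, dtype=str, keep_default_na=False)


def parse_tracking_log(
    demographics: str | Path | pd.DataFrame,
    encounters: str | Path | pd.DataFrame,
    taxonomy: SDoHTaxonomy | None = None,
) -> tuple[list[Patient], list[Encounter]]:
    """Parse a demographics table and an encounter table into records.

    Row order is preserved; missing cells become the missing sentinel (or
    ``None`` for numerics, note text and code lists) and are *not* imputed
    here.  Unknown columns are ignored with a logged warning.

    Raises
    ------
    SchemaError
        if a mandatory column is absent (the message names the column).
    ReferentialError
        if encounters reference ids with no demographics row (the message
        lists the offending ids).
    """
    taxonomy = taxonomy or default_taxonomy()
    demo = _read_table(demographics)
    enc = _read_table(encounters)

    for col in ("patient_id",) + PATIENT_CATEGORICAL + PATIENT_NUMERIC:
        if col not in demo.columns:
            raise SchemaError(f"demographics table missing mandatory column {col!r}")
    mandatory_enc = [
        c
        for c in ENCOUNTER_COLUMNS
        if c not in OPTIONAL_ENCOUNTER_COLUMNS
    ]
    for col in mandatory_enc:
        if col not in enc.columns:
            raise SchemaError(f"encounters table missing mandatory column {col!r}")

    unknown = [c for c in demo.columns if c not in DEMOGRAPHICS_COLUMNS]
    unknown += [c for c in enc.columns if c not in ENCOUNTER_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown columns: %s", ", ".join(sorted(unknown)))

    patients: list[Patient] = []
    for _, row in demo.iterrows():
        patients.append(
            Patient(
                patient_id=str(row["patient_id"]).strip(),
                age=_norm_numeric(row["age"]),
                year_arrived_us=_norm_numeric(row["year_arrived_us"]),
                household_size=_norm_numeric(row["household_size"]),
                site=_norm_cell(row["site"]) if "site" in demo.columns else "A",
                **{c: _norm_cell(row[c]) for c in PATIENT_CATEGORICAL},
            )
        )

    known_ids = {p.patient_id for p in patients}
    bad_ids = sorted(
        {str(r).strip() for r in enc["patient_id"] if str(r).strip() not in known_ids}
    )
    if bad_ids:
        raise ReferentialError(
            "encounters reference unknown patient ids: " + ", ".join(bad_ids)
        )

    encounter_list: list[Encounter] = []
    for _, row in enc.iterrows():
        if "comments" in enc.columns:
            raw_comment = str(row["comments"])
            comments = None if raw_comment.strip().lower() in NA_TOKENS else raw_comment
        else:
            comments = None
        raw_codes = _norm_cell(row["sdoh_codes"])
        if raw_codes == MISSING:
            codes: list[str] | None = None
        else:
            codes = [c.strip() for c in raw_codes.split(CODE_SEP) if c.strip()]
            for c in codes:
                if not taxonomy.is_valid(c) and c not in taxonomy.site_b_codes():
                    logger.warning("encounter code %r outside taxonomy", c)
        encounter_list.append(
            Encounter(
                patient_id=str(row["patient_id"]).strip(),
                date=_norm_cell(row["date"]) if "date" in enc.columns else MISSING,
                action_length=_norm_numeric(row["action_length"]),
                comments=comments,
                sdoh_codes=codes,
                **{c: _norm_cell(row[c]) for c in ENCOUNTER_CATEGORICAL},
            )
        )
    return patients, encounter_list


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        d = {f.name: getattr(p, f.name) for f in fields(Patient)}
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(DEMOGRAPHICS_COLUMNS))
    return df


def encounters_to_frame(encounters: Iterable[Encounter]) -> pd.DataFrame:
    rows = []
    for e in encounters:
        d = {f.name: getattr(e, f.name) for f in fields(Encounter)}
        d["comments"] = "" if e.comments is None else e.comments
        d["sdoh_codes"] = (
            "" if e.sdoh_codes is None else CODE_SEP.join(e.sdoh_codes)
        )
        rows.append(d)
    return pd.DataFrame(rows, columns=list(ENCOUNTER_COLUMNS))


def write_tracking_log(
    patients: Sequence[Patient],
    encounters: Sequence[Encounter],
    demographics_path: str | Path,
    encounters_path: str | Path,
    *,
    include_comments: bool = True,
) -> None:
    """Write the two log tables as UTF-8 CSV with header rows."""
    pdf = patients_to_frame(patients)
    edf = encounters_to_frame(encounters)
    if not include_comments:
        edf = edf.drop(columns=["comments"])
    pdf.to_csv(demographics_path, index=False)
    edf.to_csv(encounters_path, index=False)


@dataclass
class ImputationLog:
    """Counts of imputations performed and encounters dropped."""

    numeric_imputed: dict[str, int] = field(default_factory=dict)
    categorical_imputed: dict[str, int] = field(default_factory=dict)
    encounters_dropped_no_comments: int = 0
    encounters_dropped_no_codes: int = 0


def _mean_of(values: list[float], column: str) -> float:
    if not values:
        raise ImputationError(f"column {column!r} has no observed values to impute from")
    return float(np.mean(values))


def _mode_of(values: list[str], column: str) -> str:
    if not values:
        raise ImputationError(f"column {column!r} has no observed values to impute from")
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    # tie-break: lexicographically smallest among maximal counts
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def impute_missing(
    patients: Sequence[Patient],
    encounters: Sequence[Encounter],
    *,
    drop_encounters_missing_text_or_codes: bool = True,
) -> tuple[list[Patient], list[Encounter], ImputationLog]:
    """Fill missing demographic/encounter cells; drop unusable encounters.

    Numeric blanks take the arithmetic mean of observed values in the same
    column; categorical blanks take the most common observed value
    (lexicographically smallest on ties).  Encounters whose note text or
    SDoH code list was never recorded are excluded from strategy inputs
    when ``drop_encounters_missing_text_or_codes`` is set (the site-B /
    harmonization path disables the comment rule since that log has none).
    Non-missing cells are never changed.
    """
    log = ImputationLog()
    out_patients = [replace(p) for p in patients]
    out_encounters = [replace(e) for e in encounters]

    for col in PATIENT_NUMERIC:
        observed = [getattr(p, col) for p in out_patients if getattr(p, col) is not None]
        n_missing = sum(1 for p in out_patients if getattr(p, col) is None)
        if n_missing:
            mean = _mean_of(observed, col)
            for p in out_patients:
                if getattr(p, col) is None:
                    setattr(p, col, mean)
            log.numeric_imputed[col] = n_missing
    for col in PATIENT_CATEGORICAL:
        observed = [getattr(p, col) for p in out_patients if getattr(p, col) != MISSING]
        n_missing = sum(1 for p in out_patients if getattr(p, col) == MISSING)
        if n_missing:
            mode = _mode_of(observed, col)
            for p in out_patients:
                if getattr(p, col) == MISSING:
                    setattr(p, col, mode)
            log.categorical_imputed[col] = n_missing

    for col in ENCOUNTER_NUMERIC:
        observed = [getattr(e, col) for e in out_encounters if getattr(e, col) is not None]
        n_missing = sum(1 for e in out_encounters if getattr(e, col) is None)
        if n_missing:
            mean = _mean_of(observed, col)
            for e in out_encounters:
                if getattr(e, col) is None:
                    setattr(e, col, mean)
            log.numeric_imputed[col] = n_missing
    for col in ENCOUNTER_CATEGORICAL:
        observed = [getattr(e, col) for e in out_encounters if getattr(e, col) != MISSING]
        n_missing = sum(1 for e in out_encounters if getattr(e, col) == MISSING)
        if n_missing:
            mode = _mode_of(observed, col)
            for e in out_encounters:
                if getattr(e, col) == MISSING:
                    setattr(e, col, mode)
            log.categorical_imputed[col] = n_missing

    if drop_encounters_missing_text_or_codes:
        kept: list[Encounter] = []
        for e in out_encounters:
            if not e.has_comments():
                log.encounters_dropped_no_comments += 1
                continue
            if not e.has_codes():
                log.encounters_dropped_no_codes += 1
                continue
            kept.append(e)
        out_encounters = kept

    if log.numeric_imputed or log.categorical_imputed:
        logger.info(
            "imputed %s numeric and %s categorical cells; dropped %d encounters",
            sum(log.numeric_imputed.values()),
            sum(log.categorical_imputed.values()),
            log.encounters_dropped_no_comments + log.encounters_dropped_no_codes,
        )
    return out_patients, out_encounters, log


# ---------------------------------------------------------------------------
# One-hot encoding


def one_hot_encode(
    table: pd.DataFrame,
    categorical_columns: Sequence[str],
    *,
    dictionary: dict[str, list[str]] | None = None,
    unseen: str = "error",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Binarize categorical columns; numeric columns pass through unchanged.

    Each categorical value becomes a 0/1 column named ``col=value``.  The
    returned dictionary maps each original column to its ordered value list
    and permits an exact inverse (:func:`one_hot_decode`).  When a
    ``dictionary`` from a previous fit is supplied, unseen values either
    raise (``unseen='error'``, default) or produce an all-zero segment
    (``unseen='zeros'``).
    """
    if unseen not in ("error", "zeros"):
        raise ValueError(f"unseen must be 'error' or 'zeros', got {unseen!r}")
    for col in categorical_columns:
        if col not in table.columns:
            raise KeyError(f"categorical column {col!r} not in table")
        if (table[col].astype(str) == MISSING).any():
            raise ValueError(f"column {col!r} still contains missing values")

    if dictionary is None:
        dictionary = {
            col: sorted(table[col].astype(str).unique()) for col in categorical_columns
        }

    pieces: list[pd.DataFrame] = []
    for col in table.columns:
        if col in categorical_columns:
            values = table[col].astype(str)
            known = set(dictionary[col])
            unknown_mask = ~values.isin(known)
            if unknown_mask.any() and unseen == "error":
                bad = sorted(values[unknown_mask].unique())
                raise ValueError(f"unseen categories in column {col!r}: {bad}")
            block = pd.DataFrame(
                {f"{col}={v}": (values == v).astype(int) for v in dictionary[col]},
                index=table.index,
            )
            pieces.append(block)
        else:
            pieces.append(table[[col]])
    encoded = pd.concat(pieces, axis=1)
    return encoded, dictionary


def one_hot_decode(
    encoded: pd.DataFrame, dictionary: dict[str, list[str]]
) -> pd.DataFrame:
    """Exact inverse of :func:`one_hot_encode` for in-dictionary rows."""
    out: dict[str, object] = {}
    consumed: set[str] = set()
    for col, values in dictionary.items():
        block_cols = [f"{col}={v}" for v in values]
        consumed.update(block_cols)
        block = encoded[block_cols].to_numpy()
        idx = block.argmax(axis=1)
        if not (block.sum(axis=1) == 1).all():
            raise ValueError(f"encoded segment for {col!r} is not one-hot")
        out[col] = [values[i] for i in idx]
    decoded = pd.DataFrame(out, index=encoded.index)
    passthrough = [c for c in encoded.columns if c not in consumed]
    decoded = pd.concat([decoded, encoded[passthrough]], axis=1)
    return decoded


def save_column_dictionary(dictionary: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dictionary, indent=2, sort_keys=True))


def load_column_dictionary(path: str | Path) -> dict[str, list[str]]:
    return json.loads(Path(path).read_text())
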