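"""Experiment-2 data preparation: codebook harmonization and augmentation.

Two navigation studies recorded incompatible codebooks.  This module maps
site-B generic/specific SDoH codes onto the site-A taxonomy (specific
match first, generic parent as fallback, ``other`` as last resort),
consolidates per-patient barrier and intervention lists into their three
most frequent values, bins encounter intensity into L/M/H/VH around the
cohort mean and SD, and augments each record with travel information
(nearest hospital, distance, drive and transit time) looked up by zip
code through a pluggable provider — no live map service is contacted.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .data_model import MISSING, Encounter, Patient, one_hot_encode
from .taxonomy import NONE_CODE, OTHER_CODE, SDoHTaxonomy, default_taxonomy

logger = logging.getLogger(__name__)

#: Demographic attributes shared by both sites after recoding.
SHARED_ATTRIBUTES = (
    "age",
    "marital_status",
    "education_level",
    "income_range",
    "origin",
    "zip_code",
    "household_size",
    "employment",
)

#: Site-B 3-level employment recoded toward the richer site-A occupation
#: codebook.
EMPLOYMENT_RECODE_B = {
    "unemployed": "unemployed",
    "part-time": "part_time",
    "full time": "full_time",
}


# ---------------------------------------------------------------------------
# Code mapping


def map_sdoh_code(site_b_code: str, alias_map: dict[str, str]) -> str:
    """Unified code for a site-B ``generic`` or ``generic:specific`` code.

    A specific code with a direct correspondence wins; otherwise its
    generic parent's correspondence applies; a code absent from the alias
    map entirely becomes ``other``.
    """
    code = site_b_code.strip()
    if code in alias_map:
        return alias_map[code]
    generic = code.split(":", 1)[0]
    if generic in alias_map:
        return alias_map[generic]
    return OTHER_CODE


# ---------------------------------------------------------------------------
# Top-k consolidation


def top_k_labels(codes: Sequence[str], k: int = 3) -> list[str]:
    """The up-to-k most frequent codes, descending.

    Ties break by first occurrence in the list, then lexicographically.
    Fewer than k distinct codes simply yield a shorter list.
    """
    first_seen: dict[str, int] = {}
    counts: Counter = Counter()
    for i, c in enumerate(codes):
        counts[c] += 1
        first_seen.setdefault(c, i)
    ranked = sorted(counts, key=lambda c: (-counts[c], first_seen[c], c))
    return ranked[:k]


# ---------------------------------------------------------------------------
# Intensity bins


@dataclass(frozen=True)
class IntensityBins:
    """L/M/H/VH encounter-count thresholds anchored at mean and SD.

    ``thresholds = (t1, t2, t3)``: counts below t1 are L, counts in
    [t1, t2) are M, counts in [t2, t3] are H, counts above t3 are VH.
    """

    thresholds: tuple[int, int, int]
    mean: float = float("nan")
    sd: float = float("nan")
    labels: tuple[str, str, str, str] = ("L", "M", "H", "VH")

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not t1 < t2 < t3:
            raise ValueError(f"thresholds must be strictly increasing, got {self.thresholds}")


def paper_bins() -> IntensityBins:
    """The fixed published thresholds (3, 16, 29) with the printed moments."""
    return IntensityBins(thresholds=(3, 16, 29), mean=16.94, sd=13.06)


def derive_bins(counts: Sequence[int]) -> IntensityBins:
    """Recompute thresholds from a count vector as round(mean-sd, mean, mean+sd)."""
    if len(counts) == 0:
        raise ValueError("cannot derive bins from an empty count vector")
    arr = np.asarray(counts, dtype=float)
    mean, sd = float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if sd == 0.0:
        raise ValueError(
            "encounter counts have zero spread; choose fixed thresholds instead"
        )
    t1, t2, t3 = (int(round(mean - sd)), int(round(mean)), int(round(mean + sd)))
    return IntensityBins(thresholds=(t1, t2, t3), mean=mean, sd=sd)


def intensity_bin(count: int, bins: IntensityBins) -> str:
    """Assign one count to L, M, H or VH; boundaries are [t1,t2) M, [t2,t3] H."""
    if count < 0:
        raise ValueError(f"encounter count must be nonnegative, got {count}")
    t1, t2, t3 = bins.thresholds
    low, med, high, very_high = bins.labels
    if count < t1:
        return low
    if count < t2:
        return med
    if count <= t3:
        return high
    return very_high


# ---------------------------------------------------------------------------
# Travel provider


@dataclass(frozen=True)
class TravelInfo:
    hospital_id: str
    distance_km: float
    drive_minutes: float
    transit_minutes: float | None


class TravelProvider(Protocol):
    """Zip-code lookup of nearest-hospital travel figures."""

    def lookup(self, zip_code: str) -> TravelInfo: ...


class FixtureTravelProvider:
    """Deterministic provider backed by an in-memory or CSV fixture table."""

    def __init__(self, table: dict[str, TravelInfo]):
        self._table = dict(table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FixtureTravelProvider":
        df = pd.read_csv(path, dtype={"zip": str})
        table = {}
        for _, row in df.iterrows():
            transit = row.get("transit_min")
            table[str(row["zip"])] = TravelInfo(
                hospital_id=str(row["hospital"]),
                distance_km=float(row["km"]),
                drive_minutes=float(row["drive_min"]),
                transit_minutes=None if pd.isna(transit) else float(transit),
            )
        return cls(table)

    def lookup(self, zip_code: str) -> TravelInfo:
        return self._table[str(zip_code)]


#: Synthetic hospital sites (id, lat, lon) for the coordinate provider.
_HOSPITALS = (
    ("H_CENTRAL", 41.850, -87.650),
    ("H_WEST", 41.870, -87.800),
    ("H_SOUTH", 41.750, -87.620),
    ("H_NORTHWEST", 41.950, -87.760),
)


class SyntheticTravelProvider:
    """Haversine travel figures on synthetic zip-code coordinates.

    A zip code maps deterministically to a pseudo-coordinate; the nearest
    of a fixed synthetic hospital list supplies distance, a 40 km/h drive
    estimate, and a transit estimate that is absent for a deterministic
    subset of zips (emulating patchy transit coverage).
    """

    def _coords(self, zip_code: str) -> tuple[float, float]:
        h = abs(hash(("zip", zip_code))) % 10_000
        lat = 41.70 + (h % 100) / 100 * 0.30
        lon = -87.90 + (h // 100) / 100 * 0.35
        return lat, lon

    @staticmethod
    def _haversine(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
        r = 6371.0
        p1, p2 = math.radians(lat1), math.radians(lat2)
        dp, dl = math.radians(lat2 - lat1), math.radians(lon2 - lon1)
        a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
        return 2 * r * math.asin(math.sqrt(a))

    def lookup(self, zip_code: str) -> TravelInfo:
        lat, lon = self._coords(zip_code)
        best = min(
            _HOSPITALS, key=lambda h: self._haversine(lat, lon, h[1], h[2])
        )
        km = self._haversine(lat, lon, best[1], best[2])
        drive = 5.0 + km / 40.0 * 60.0
        transit: float | None = round(drive * 2.2, 1)
        if int("".join(ch for ch in zip_code if ch.isdigit()) or "0") % 7 == 0:
            transit = None
        return TravelInfo(best[0], round(km, 2), round(drive, 1), transit)


# ---------------------------------------------------------------------------
# Harmonization


def _clean_value(value: object, observed_codes: set[str]) -> str:
    """Value-conversion rules for categorical cells during consolidation."""
    s = str(value)
    if not s.isascii():
        return NONE_CODE  # foreign-language entry
    if s == MISSING:
        if "chose_not_to_answer" in observed_codes:
            return "chose_not_to_answer"
        if OTHER_CODE in observed_codes:
            return OTHER_CODE
        return NONE_CODE
    return s


def harmonize(
    site_a: tuple[Sequence[Patient], Sequence[Encounter]],
    site_b: tuple[Sequence[Patient], Sequence[Encounter]],
    taxonomy: SDoHTaxonomy | None = None,
    *,
    top_k: int = 3,
) -> pd.DataFrame:
    """Consolidate both sites into one unified patient table.

    Only attributes shared by both sites survive; values recode toward the
    richer codebook (site-B 3-level employment joins site-A occupation
    categories); per-patient SDoH and intervention lists consolidate into
    the ``top_k`` most frequent codes; patients without any navigation
    encounter are excluded; numeric blanks take the column mean.
    """
    taxonomy = taxonomy or default_taxonomy()
    rows: list[dict] = []
    for site, (patients, encounters) in (("A", site_a), ("B", site_b)):
        by_patient: dict[str, list[Encounter]] = {p.patient_id: [] for p in patients}
        for e in encounters:
            if e.patient_id in by_patient:
                by_patient[e.patient_id].append(e)
        for p in patients:
            encs = by_patient[p.patient_id]
            if not encs:
                logger.info("excluding %s: no navigation encounters", p.patient_id)
                continue
            codes: list[str] = []
            interventions: list[str] = []
            for e in encs:
                for c in e.sdoh_codes or ():
                    codes.append(c if site == "A" else map_sdoh_code(c, taxonomy.alias_map))
                if e.action_taken != MISSING:
                    interventions.append(str(e.action_taken))
            employment = (
                str(p.occupation)
                if site == "A"
                else EMPLOYMENT_RECODE_B.get(str(p.occupation), str(p.occupation))
            )
            row = {
                "patient_id": p.patient_id,
                "site": site,
                "age": p.age,
                "marital_status": p.marital_status,
                "education_level": p.education_level,
                "income_range": p.income_range,
                "origin": p.origin,
                "zip_code": p.zip_code,
                "household_size": p.household_size,
                "employment": employment,
                "encounter_count": len(encs),
            }
            top_barriers = top_k_labels(codes, k=top_k)
            top_actions = top_k_labels(interventions, k=top_k)
            for j in range(top_k):
                row[f"barrier_{j + 1}"] = top_barriers[j] if j < len(top_barriers) else ""
                row[f"intervention_{j + 1}"] = (
                    top_actions[j] if j < len(top_actions) else ""
                )
            rows.append(row)

    df = pd.DataFrame(rows)
    # categorical cleanup: foreign-language and unspecified values
    cat_cols = [c for c in SHARED_ATTRIBUTES if c not in ("age", "household_size")]
    for col in cat_cols:
        observed = set(df[col].astype(str)) - {MISSING}
        df[col] = [
            _clean_value(v, observed) for v in df[col]
        ]
    # numeric blanks -> column mean
    for col in ("age", "household_size"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().all():
            raise ValueError(f"numeric column {col!r} has no observed values")
        df[col] = vals.fillna(vals.mean())
    return df


def assign_intensity(records: pd.DataFrame, bins: IntensityBins) -> pd.DataFrame:
    """Add the L/M/H/VH ``encounter_range`` column."""
    out = records.copy()
    out["encounter_range"] = [
        intensity_bin(int(c), bins) for c in out["encounter_count"]
    ]
    return out


def travel_augment(records: pd.DataFrame, provider: TravelProvider) -> pd.DataFrame:
    """Fill nearest-hospital travel fields from the provider, by zip code.

    Provider failures leave the fields missing; absent transit times are
    replaced by the mean of the observed transit times.  If no transit
    time is observed at all, a default must be supplied upstream.
    """
    out = records.copy()
    hospital, km, drive, transit = [], [], [], []
    for z in out["zip_code"].astype(str):
        try:
            info = provider.lookup(z)
        except KeyError:
            logger.warning("travel provider has no entry for zip %r", z)
            hospital.append(MISSING)
            km.append(np.nan)
            drive.append(np.nan)
            transit.append(np.nan)
            continue
        hospital.append(info.hospital_id)
        km.append(info.distance_km)
        drive.append(info.drive_minutes)
        transit.append(np.nan if info.transit_minutes is None else info.transit_minutes)
    out["nearest_hospital_id"] = hospital
    out["distance_km"] = km
    out["drive_minutes"] = drive
    out["transit_minutes"] = transit
    observed = out["transit_minutes"].dropna()
    if out["transit_minutes"].isna().any():
        if observed.empty:
            raise ValueError(
                "no transit time observed for any zip; supply a default transit time"
            )
        out["transit_minutes"] = out["transit_minutes"].fillna(observed.mean())
    for col in ("distance_km", "drive_minutes"):
        if out[col].isna().any() and out[col].notna().any():
            out[col] = out[col].fillna(out[col].dropna().mean())
    return out


def binarize_strings(
    records: pd.DataFrame,
    taxonomy: SDoHTaxonomy | None = None,
    *,
    include_none_class: bool = True,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Binary feature matrix, column dictionary, and multi-label targets.

    String attribute columns one-hot encode (numeric columns pass
    through); the target frame has one 0/1 column per unified SDoH code,
    set for each of the patient's top-3 barriers, so row sums are <= 3.
    ``include_none_class=False`` drops the pervasive wildcard class.
    """
    taxonomy = taxonomy or default_taxonomy()
    feature_cols = [
        c
        for c in records.columns
        if c not in ("patient_id", "barrier_1", "barrier_2", "barrier_3")
    ]
    table = records[feature_cols]
    categorical = [
        c for c in feature_cols if table[c].dtype == object and c != "encounter_count"
    ]
    X, dictionary = one_hot_encode(table, categorical)

    classes = list(taxonomy.codes) + [OTHER_CODE]
    if include_none_class:
        classes.append(NONE_CODE)
    Y = pd.DataFrame(0, index=records.index, columns=[f"sdoh_{c}" for c in classes])
    for j in (1, 2, 3):
        col = f"barrier_{j}"
        if col not in records.columns:
            continue
        for i, code in records[col].items():
            if code and f"sdoh_{code}" in Y.columns:
                Y.loc[i, f"sdoh_{code}"] = 1
    return X, dictionary, Y
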