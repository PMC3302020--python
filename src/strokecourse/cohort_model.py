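"""Domain model for an acute cerebral ischaemia cohort.

Patients are described by serial neurological assessments on two
instruments:

* the NIHSS (National Institutes of Health Stroke Scale), the standard
  15-item severity instrument with a total of 0-42 (higher = worse),
  scored prehospital by the referring general practitioner ("GP" source,
  reconstructed by structured phone interview), on admission, every
  8 hours during the first day, at 24 hours, and at discharge;
* the NDS (Neurological Dysfunction Score), an 11-item patient/family
  reported deficit instrument, each item an ordinal level 0 (normal) to
  3 (worst), total 0-33, recorded at symptom onset (NDS-0) and on
  admission (NDS-1).

Any item may be "unknown" (held as ``None``); totals are computed over
known items only, never imputed here.  Discharge outcome is the modified
Rankin Scale (mRS, 0-5) with death held internally as a sixth level so
that outcome dichotomies are pure set membership.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "NIHSS_ITEMS",
    "NDS_ITEMS",
    "NIHSS_SOURCES",
    "DEATH",
    "MRS_LEVELS",
    "NIHSSAssessment",
    "NDSAssessment",
    "PatientRecord",
    "OutcomeDichotomy",
    "GOOD_VS_REST",
    "POOR_VS_REST",
    "DEPENDENT_OR_DEAD_VS_REST",
    "ScoreTotal",
    "score_total",
    "dichotomize",
    "IncompleteAssessmentError",
    "CohortValidationError",
    "write_cohort_csv",
    "read_cohort_csv",
    "column_schema",
    "write_schema_json",
]

# Standard 15-item NIHSS with per-item maxima; maxima sum to 42.
NIHSS_ITEMS: dict[str, int] = {
    "loc": 3,
    "loc_questions": 2,
    "loc_commands": 2,
    "gaze": 2,
    "visual": 3,
    "facial_palsy": 3,
    "motor_arm_left": 4,
    "motor_arm_right": 4,
    "motor_leg_left": 4,
    "motor_leg_right": 4,
    "ataxia": 2,
    "sensory": 2,
    "language": 3,
    "dysarthria": 2,
    "neglect": 2,
}

# 11 NDS items, each ordinal 0 (normal) .. 3 (worst); maxima sum to 33.
NDS_ITEMS: dict[str, int] = {
    "motor_face": 3,
    "motor_upper_limb": 3,
    "motor_lower_limb": 3,
    "sensory_face": 3,
    "sensory_upper_limb": 3,
    "sensory_lower_limb": 3,
    "cognitive": 3,
    "upright_position": 3,
    "gait": 3,
    "coordination_upper_limb": 3,
    "coordination_lower_limb": 3,
}

NIHSS_SOURCES = ("gp", "admission", "h8", "h16", "h24", "discharge")
NDS_TAGS = ("0", "1")  # NDS-0 (symptom onset, prehospital) and NDS-1 (admission)

DEATH = 6  # mRS death level, internal encoding; I/O writes the literal "death"
MRS_LEVELS = frozenset(range(7))

ONSET_TYPES = ("sudden", "progressive", "unknown")
CATEGORIES = ("lesion_free_TIA", "TIA_with_lesion", "infarction")


class IncompleteAssessmentError(ValueError):
    """Raised when an operation needs at least one known item and has none."""


class CohortValidationError(ValueError):
    """Raised for records or values violating the domain invariants."""


def _validate_items(items: Mapping[str, Optional[int]], template: Mapping[str, int],
                    what: str) -> dict[str, Optional[int]]:
    if set(items) != set(template):
        missing = set(template) - set(items)
        extra = set(items) - set(template)
        raise CohortValidationError(
            f"{what} items mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
    out: dict[str, Optional[int]] = {}
    for name, mx in template.items():
        v = items[name]
        if v is None:
            out[name] = None
            continue
        v = int(v)
        if not 0 <= v <= mx:
            raise CohortValidationError(
                f"{what} item {name!r}={v} outside [0, {mx}]")
        out[name] = v
    return out


@dataclass(frozen=True)
class NIHSSAssessment:
    """One itemized NIHSS examination.

    Parameters
    ----------
    timestamp
        Minutes since symptom onset.
    items
        Mapping of the 15 standard item names to an integer in the item's
        range, or ``None`` for an unknown / unassessed item.
    source
        Which examination this is: ``gp`` (prehospital, reconstructed from
        the general practitioner), ``admission``, ``h8``, ``h16``, ``h24``
        or ``discharge``.
    """

    timestamp: int
    items: Mapping[str, Optional[int]]
    source: str

    def __post_init__(self) -> None:
        if self.source not in NIHSS_SOURCES:
            raise CohortValidationError(f"unknown NIHSS source {self.source!r}")
        object.__setattr__(self, "items",
                           _validate_items(self.items, NIHSS_ITEMS, "NIHSS"))

    @property
    def incomplete(self) -> bool:
        """True when every item is unknown (total undefined)."""
        return all(v is None for v in self.items.values())


@dataclass(frozen=True)
class NDSAssessment:
    """One itemized NDS evaluation (11 ordinal items, levels 0-3)."""

    timestamp: int
    items: Mapping[str, Optional[int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items",
                           _validate_items(self.items, NDS_ITEMS, "NDS"))

    @property
    def incomplete(self) -> bool:
        return all(v is None for v in self.items.values())


class ScoreTotal(NamedTuple):
    total: int
    n_unknown: int


Assessment = Union[NIHSSAssessment, NDSAssessment]


def score_total(assessment: Assessment) -> ScoreTotal:
    """Total over known items plus the count of unknown items.

    Unknown items are excluded, never imputed.  Raises
    :class:`IncompleteAssessmentError` when every item is unknown.
    """
    known = [v for v in assessment.items.values() if v is not None]
    if not known:
        raise IncompleteAssessmentError(
            "assessment has no known items; total undefined")
    return ScoreTotal(total=int(sum(known)),
                      n_unknown=len(assessment.items) - len(known))


@dataclass(frozen=True)
class OutcomeDichotomy:
    """A binary outcome defined as membership of a set of mRS levels."""

    name: str
    positive_set: frozenset[int]

    def __post_init__(self) -> None:
        ps = frozenset(self.positive_set)
        if not ps or not ps < MRS_LEVELS:
            raise CohortValidationError(
                "positive_set must be a non-empty proper subset of mRS levels 0-6")
        object.__setattr__(self, "positive_set", ps)


#: Good outcome: slight or no disability (mRS 0-1).
GOOD_VS_REST = OutcomeDichotomy("good_vs_rest", frozenset({0, 1}))
#: Poor outcome: dependent (mRS 4-5) or dead.
POOR_VS_REST = OutcomeDichotomy("poor_vs_rest", frozenset({4, 5, DEATH}))
#: mRS 4-5 or death versus mRS 0-3, used for association testing.
DEPENDENT_OR_DEAD_VS_REST = OutcomeDichotomy(
    "dependent_or_dead_vs_rest", frozenset({4, 5, DEATH}))


def dichotomize(mrs: int, dichotomy: OutcomeDichotomy) -> int:
    """1 iff the mRS level falls in the dichotomy's positive set."""
    if mrs not in MRS_LEVELS:
        raise CohortValidationError(f"mRS level {mrs!r} outside 0-6")
    return int(mrs in dichotomy.positive_set)


@dataclass
class PatientRecord:
    """One patient's timestamps, serial assessments, plateau, category and
    discharge outcome.

    All times are integer minutes since symptom onset (onset_time is 0 by
    convention but kept explicit).  Eligible patients are admitted within
    24 hours (admission_time <= 1440).
    """

    id: str
    onset_type: str
    onset_time: int
    admission_time: int
    nds_series: Sequence[NDSAssessment] = field(default_factory=list)
    nihss_series: Sequence[NIHSSAssessment] = field(default_factory=list)
    plateau_anamnesis_min: Optional[int] = None
    category: str = "infarction"
    mrs_discharge: int = 0

    def __post_init__(self) -> None:
        if self.onset_type not in ONSET_TYPES:
            raise CohortValidationError(f"unknown onset_type {self.onset_type!r}")
        if self.category not in CATEGORIES:
            raise CohortValidationError(f"unknown category {self.category!r}")
        if self.mrs_discharge not in MRS_LEVELS:
            raise CohortValidationError(
                f"mRS level {self.mrs_discharge!r} outside 0-6")
        for series in (self.nds_series, self.nihss_series):
            ts = [a.timestamp for a in series]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise CohortValidationError(
                    f"patient {self.id}: series timestamps not strictly increasing")

    def nihss(self, source: str) -> Optional[NIHSSAssessment]:
        """The NIHSS assessment from a given source, or None."""
        for a in self.nihss_series:
            if a.source == source:
                return a
        return None

    @property
    def nds_0(self) -> Optional[NDSAssessment]:
        return self.nds_series[0] if len(self.nds_series) >= 1 else None

    @property
    def nds_1(self) -> Optional[NDSAssessment]:
        return self.nds_series[1] if len(self.nds_series) >= 2 else None


# ---------------------------------------------------------------------------
# CSV interchange: one wide row per patient, "NA" for unknown items and for
# absent assessments, mRS death written as the literal "death".
# ---------------------------------------------------------------------------

_PATIENT_COLS = ("id", "onset_type", "onset_time_min", "admission_time_min",
                 "plateau_anamnesis_min", "category", "mrs_discharge")


def _assessment_cols() -> list[str]:
    cols: list[str] = []
    for src in NIHSS_SOURCES:
        cols.append(f"nihss_{src}_time_min")
        cols.extend(f"nihss_{src}_{item}" for item in NIHSS_ITEMS)
    for tag in NDS_TAGS:
        cols.append(f"nds_{tag}_time_min")
        cols.extend(f"nds_{tag}_{item}" for item in NDS_ITEMS)
    return cols


def column_schema() -> dict:
    """Machine-readable description of the cohort CSV columns."""
    cols: dict[str, str] = {
        "id": "opaque patient identifier",
        "onset_type": "one of sudden|progressive|unknown",
        "onset_time_min": "symptom onset, minutes (0 by convention)",
        "admission_time_min": "hospital admission, minutes since onset",
        "plateau_anamnesis_min": "plateau duration from patient/family anamnesis, minutes, NA if missing",
        "category": "one of lesion_free_TIA|TIA_with_lesion|infarction",
        "mrs_discharge": "modified Rankin Scale at discharge, 0-5 or 'death'",
    }
    for src in NIHSS_SOURCES:
        cols[f"nihss_{src}_time_min"] = (
            f"time of NIHSS {src} examination, minutes since onset, NA if not done")
        for item, mx in NIHSS_ITEMS.items():
            cols[f"nihss_{src}_{item}"] = f"NIHSS item, 0-{mx} or NA (unknown)"
    for tag in NDS_TAGS:
        cols[f"nds_{tag}_time_min"] = (
            f"time of NDS-{tag} evaluation, minutes since onset, NA if not done")
        for item in NDS_ITEMS:
            cols[f"nds_{tag}_{item}"] = "NDS item, ordinal 0-3 or NA (unknown)"
    return {
        "format": "one row per patient, wide columns per assessment source and item",
        "na_token": "NA",
        "columns": cols,
    }


def write_schema_json(path) -> None:
    with open(path, "w") as fh:
        json.dump(column_schema(), fh, indent=2)


def _fmt(v) -> str:
    return "NA" if v is None else str(int(v))


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    rows = []
    for r in records:
        row: dict[str, str] = {
            "id": r.id,
            "onset_type": r.onset_type,
            "onset_time_min": str(int(r.onset_time)),
            "admission_time_min": str(int(r.admission_time)),
            "plateau_anamnesis_min": _fmt(r.plateau_anamnesis_min),
            "category": r.category,
            "mrs_discharge": "death" if r.mrs_discharge == DEATH else str(r.mrs_discharge),
        }
        for src in NIHSS_SOURCES:
            a = r.nihss(src)
            row[f"nihss_{src}_time_min"] = _fmt(a.timestamp if a else None)
            for item in NIHSS_ITEMS:
                row[f"nihss_{src}_{item}"] = _fmt(a.items[item] if a else None)
        for tag, a in zip(NDS_TAGS, (r.nds_0, r.nds_1)):
            row[f"nds_{tag}_time_min"] = _fmt(a.timestamp if a else None)
            for item in NDS_ITEMS:
                row[f"nds_{tag}_{item}"] = _fmt(a.items[item] if a else None)
        rows.append(row)
    cols = list(_PATIENT_COLS) + _assessment_cols()
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _parse(v: str) -> Optional[int]:
    return None if v in ("NA", "") else int(v)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records: list[PatientRecord] = []
    for _, row in df.iterrows():
        nihss_series = []
        for src in NIHSS_SOURCES:
            ts = _parse(row[f"nihss_{src}_time_min"])
            if ts is None:
                continue
            items = {item: _parse(row[f"nihss_{src}_{item}"]) for item in NIHSS_ITEMS}
            nihss_series.append(NIHSSAssessment(timestamp=ts, items=items, source=src))
        nihss_series.sort(key=lambda a: a.timestamp)
        nds_series = []
        for tag in NDS_TAGS:
            ts = _parse(row[f"nds_{tag}_time_min"])
            if ts is None:
                continue
            items = {item: _parse(row[f"nds_{tag}_{item}"]) for item in NDS_ITEMS}
            nds_series.append(NDSAssessment(timestamp=ts, items=items))
        mrs = row["mrs_discharge"]
        records.append(PatientRecord(
            id=row["id"],
            onset_type=row["onset_type"],
            onset_time=int(row["onset_time_min"]),
            admission_time=int(row["admission_time_min"]),
            nds_series=nds_series,
            nihss_series=nihss_series,
            plateau_anamnesis_min=_parse(row["plateau_anamnesis_min"]),
            category=row["category"],
            mrs_discharge=DEATH if mrs == "death" else int(mrs),
        ))
    return records
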