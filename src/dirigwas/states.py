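"""Hypertension state assignment and per-subject state sequences.

Blood pressure at each examination is collapsed into a three-level ordinal
state: normotensive (1), prehypertensive (2) and hypertensive (3), following
the standard clinical cut-offs (120/80 and 140/90 mm Hg).  Use of
antihypertensive medication forces state 3 regardless of the recorded
pressures, since treated pressure readings do not reflect the untreated
phenotype.  Exams with any missing clinical variable are excluded before
state assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

STATE_NORMAL = 1
STATE_PREHYPERTENSIVE = 2
STATE_HYPERTENSIVE = 3

#: Clinical variables that must all be present for an exam to be retained.
CLINICAL_FIELDS = ("sbp", "dbp", "meds", "sex", "smoke", "age")

#: Default phenotype CSV column names; override via ``column_map``.
DEFAULT_COLUMNS = {
    "subject_id": "subject_id",
    "family_id": "family_id",
    "exam": "exam",
    "sbp": "sbp",
    "dbp": "dbp",
    "meds": "meds",
    "sex": "sex",
    "smoke": "smoke",
    "age": "age",
}


class InvalidRecordError(ValueError):
    """Raised when a state is requested for an exam with missing clinical data."""


@dataclass(frozen=True)
class ExamRecord:
    """One examination of one subject.

    ``sbp``/``dbp`` are systolic/diastolic blood pressure in mm Hg, ``meds``
    flags antihypertensive-medication use.  Any clinical field may be missing
    (``None`` or NaN); such exams are dropped by :func:`build_state_sequences`.
    """

    subject_id: str
    family_id: str
    exam: int
    sbp: float | None
    dbp: float | None
    meds: bool | None
    sex: int | None
    smoke: int | None
    age: float | None

    def is_complete(self) -> bool:
        return not any(_is_missing(getattr(self, f)) for f in CLINICAL_FIELDS)


@dataclass(frozen=True)
class ExamState:
    """A retained exam with its assigned state and complete covariates."""

    exam: int
    state: int
    sex: int
    smoke: int
    age: float
    sbp: float
    dbp: float
    meds: bool


@dataclass
class StateSequence:
    """Ordered hypertension states of one subject across examinations."""

    subject_id: str
    family_id: str
    exams: list[ExamState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exams)

    @property
    def states(self) -> list[int]:
        return [e.state for e in self.exams]

    @property
    def last(self) -> ExamState:
        return self.exams[-1]


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def assign_state(sbp: float, dbp: float, meds: bool) -> int:
    """Assign the hypertension state for a single examination.

    State 3 whenever medication is used; otherwise state 1 if SBP < 120 and
    DBP < 80; state 2 if not state 1 but SBP < 140 and DBP < 90; else state 3.
    Thresholds are strict: 120/80 and 140/90 themselves belong to the higher
    state.

    Raises
    ------
    InvalidRecordError
        If any input is missing or a pressure is non-positive.
    """
    if _is_missing(sbp) or _is_missing(dbp) or _is_missing(meds):
        raise InvalidRecordError("missing sbp/dbp/meds; exam should have been excluded")
    if sbp <= 0 or dbp <= 0:
        raise InvalidRecordError(f"non-positive blood pressure: sbp={sbp}, dbp={dbp}")
    if meds:
        return STATE_HYPERTENSIVE
    if sbp < 120 and dbp < 80:
        return STATE_NORMAL
    if sbp < 140 and dbp < 90:
        return STATE_PREHYPERTENSIVE
    return STATE_HYPERTENSIVE


def build_state_sequences(records: Iterable[ExamRecord]) -> list[StateSequence]:
    """Build per-subject state sequences from exam records.

    Exams with any missing clinical variable (sbp, dbp, meds, sex, smoke,
    age) are dropped; subjects with no remaining exams are omitted.  Retained
    exams are sorted by exam index.
    """
    by_subject: dict[str, list[ExamRecord]] = {}
    family_of: dict[str, str] = {}
    order: list[str] = []
    for rec in records:
        if rec.subject_id not in by_subject:
            by_subject[rec.subject_id] = []
            family_of[rec.subject_id] = rec.family_id
            order.append(rec.subject_id)
        by_subject[rec.subject_id].append(rec)

    sequences: list[StateSequence] = []
    for sid in order:
        kept = sorted((r for r in by_subject[sid] if r.is_complete()),
                      key=lambda r: r.exam)
        if not kept:
            continue
        exams = [
            ExamState(
                exam=int(r.exam),
                state=assign_state(r.sbp, r.dbp, bool(r.meds)),
                sex=int(r.sex),
                smoke=int(r.smoke),
                age=float(r.age),
                sbp=float(r.sbp),
                dbp=float(r.dbp),
                meds=bool(r.meds),
            )
            for r in kept
        ]
        sequences.append(StateSequence(subject_id=sid, family_id=family_of[sid],
                                       exams=exams))
    return sequences


def read_phenotypes(path: str, column_map: Mapping[str, str] | None = None) -> list[ExamRecord]:
    """Read a long-format phenotype CSV (one row per subject-exam).

    ``column_map`` maps canonical field names (keys of ``DEFAULT_COLUMNS``)
    to the file's column names.  Missing values may be empty fields or NA.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file {path!r} lacks columns: {missing_cols}")

    def _get(row: pd.Series, key: str, cast):
        v = row[cols[key]]
        if pd.isna(v):
            return None
        return cast(v)

    records = []
    for _, row in df.iterrows():
        records.append(
            ExamRecord(
                subject_id=str(row[cols["subject_id"]]),
                family_id=str(row[cols["family_id"]]),
                exam=int(row[cols["exam"]]),
                sbp=_get(row, "sbp", float),
                dbp=_get(row, "dbp", float),
                meds=_get(row, "meds", lambda v: bool(int(v))),
                sex=_get(row, "sex", lambda v: int(float(v))),
                smoke=_get(row, "smoke", lambda v: int(float(v))),
                age=_get(row, "age", float),
            )
        )
    return records


def records_to_frame(records: Sequence[ExamRecord]) -> pd.DataFrame:
    """Exam records as a long-format DataFrame (canonical column names)."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "family_id": [r.family_id for r in records],
            "exam": [r.exam for r in records],
            "sbp": [r.sbp for r in records],
            "dbp": [r.dbp for r in records],
            "meds": [None if r.meds is None else int(r.meds) for r in records],
            "sex": [r.sex for r in records],
            "smoke": [r.smoke for r in records],
            "age": [r.age for r in records],
        }
    )
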