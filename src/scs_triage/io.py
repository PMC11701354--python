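"""CSV readers and writers for patients, ratings and SUS responses.

Dialect: UTF-8, header row, comma separator, booleans written as
``true``/``false``, empty cell = missing value. The patient CSV has one
row per record with columns exactly matching the PatientRecord fields;
ratings are long format (rater_id, patient_id, call); SUS responses are
wide (respondent_id, item_1..item_10).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .records import PatientRecord, RatingMatrix, SUSResponseSet
from .triage import TriageDecision

__all__ = [
    "write_patients_csv",
    "read_patients_csv",
    "write_ratings_csv",
    "read_ratings_csv",
    "write_sus_csv",
    "read_sus_csv",
    "write_decisions_csv",
]

_BOOL_FIELDS = (
    "prior_back_surgery",
    "absolute_contraindication",
    "widespread_pain",
    "substance_abuse",
    "responded_conservative",
    "prior_scs",
    "anatomic_abnormality",
)

_COLUMNS = (
    "patient_id",
    "prior_back_surgery",
    "pain_location",
    "dn4_score",
    "pain_duration_months",
    "nprs_leg",
    "nprs_back",
    "age_years",
    *_BOOL_FIELDS[1:],
)


def _bools_to_str(frame: pd.DataFrame, columns) -> pd.DataFrame:
    frame = frame.copy()
    for col in columns:
        if col in frame.columns:
            frame[col] = frame[col].map({True: "true", False: "false"})
    return frame


def write_patients_csv(records: Sequence[PatientRecord], path) -> None:
    frame = pd.DataFrame([r.model_dump() for r in records], columns=_COLUMNS)
    frame = _bools_to_str(frame, _BOOL_FIELDS)
    frame.to_csv(path, index=False, encoding="utf-8")


def read_patients_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, encoding="utf-8", dtype={"patient_id": str})
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"patient CSV lacks columns: {sorted(missing)}")
    records = []
    for row in frame.to_dict(orient="records"):
        payload = {}
        for key in _COLUMNS:
            value = row[key]
            if isinstance(value, float) and np.isnan(value):
                value = None
            if key in _BOOL_FIELDS and value is not None:
                if value not in ("true", "false", True, False):
                    raise ValueError(
                        f"column {key}: expected 'true'/'false', got {value!r}"
                    )
                value = value in ("true", True)
            if key == "dn4_score" and value is not None:
                value = int(value)
            payload[key] = value
        records.append(PatientRecord(**payload))
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("patient_id values are not unique")
    return records


def write_ratings_csv(matrix: RatingMatrix, path) -> None:
    matrix.to_long().to_csv(path, index=False, encoding="utf-8")


def read_ratings_csv(path) -> RatingMatrix:
    long = pd.read_csv(
        path, encoding="utf-8", dtype={"rater_id": str, "patient_id": str}
    )
    return RatingMatrix.from_long(long)


def write_sus_csv(responses: SUSResponseSet, path) -> None:
    frame = responses.responses.copy()
    frame.index.name = "respondent_id"
    frame.to_csv(path, encoding="utf-8")


def read_sus_csv(path) -> SUSResponseSet:
    frame = pd.read_csv(path, encoding="utf-8", dtype={"respondent_id": str})
    if "respondent_id" not in frame.columns:
        raise ValueError("SUS CSV lacks a respondent_id column")
    frame = frame.set_index("respondent_id")
    return SUSResponseSet(frame)


def write_decisions_csv(decisions: Sequence[TriageDecision], path) -> None:
    """One row per patient: outcome, review flag, per-indicator satisfaction."""
    if not decisions:
        raise ValueError("no decisions to write")
    indicator_names = list(decisions[0].satisfied)
    rows = []
    for d in decisions:
        row = {
            "patient_id": d.patient_id,
            "stage1_positive": d.stage1_positive,
            "needs_manual_review": d.needs_manual_review,
            "missing_fields": ";".join(d.missing_fields),
        }
        for name in indicator_names:
            row[f"indicator_{name}"] = d.satisfied.get(name)
        rows.append(row)
    frame = pd.DataFrame(rows)
    bool_cols = [c for c in frame.columns if c not in ("patient_id", "missing_fields")]
    frame = _bools_to_str(frame, bool_cols)
    frame.to_csv(path, index=False, encoding="utf-8")
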