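"""Domain containers: patient records, rating matrices, SUS response sets.

A :class:`PatientRecord` carries the patient-reported outcome measures
(PROMs) and referral facts that the stage-1 triage rule reads: pain scores
on the numeric pain rating scale (NPRS, 0-10), the DN4 neuropathic-pain
screener (0-10, may be missing), pain duration and location, prior-surgery
status, and the boolean exclusion flags (contraindications, widespread
pain, substance abuse, response to conservative treatment, prior SCS,
anatomic abnormalities).
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PatientRecord", "PainLocation", "RatingMatrix", "SUSResponseSet"]

PainLocation = Literal["back", "leg", "mixed"]

#: fields of PatientRecord the rule engine may reference
RULE_FIELDS = (
    "prior_back_surgery",
    "pain_location",
    "dn4_score",
    "pain_duration_months",
    "nprs_leg",
    "nprs_back",
    "age_years",
    "absolute_contraindication",
    "widespread_pain",
    "substance_abuse",
    "responded_conservative",
    "prior_scs",
    "anatomic_abnormality",
)


class PatientRecord(BaseModel):
    """One waiting-list patient's PROMs, referral facts and exclusion flags.

    Scale ranges are enforced on construction; ``dn4_score`` is the only
    field that may be missing (the DN4 questionnaire is a recent addition
    to outcome registries and is not always completed).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    patient_id: str
    prior_back_surgery: bool
    pain_location: PainLocation
    dn4_score: Optional[int] = Field(default=None, ge=0, le=10)
    pain_duration_months: float = Field(ge=0)
    nprs_leg: int = Field(ge=0, le=10)
    nprs_back: int = Field(ge=0, le=10)
    age_years: float = Field(ge=0)
    absolute_contraindication: bool = False
    widespread_pain: bool = False
    substance_abuse: bool = False
    responded_conservative: bool = False
    prior_scs: bool = False
    anatomic_abnormality: bool = False


class RatingMatrix:
    """Complete subjects x raters grid of binary eligibility calls.

    Wraps a :class:`pandas.DataFrame` whose index holds subject identifiers,
    whose columns hold rater identifiers, and whose cells are 0/1 calls.
    The design must be complete (no missing cells) — the multi-rater kappa
    is only defined for a complete grid.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.isna().any().any():
            raise ValueError(
                "rating matrix has missing cells; the multi-rater analysis "
                "requires a complete design — fall back to pairwise Cohen's "
                "kappa on the complete pairs"
            )
        values = calls.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("rating calls must be binary (0/1)")
        if calls.index.has_duplicates or calls.columns.has_duplicates:
            raise ValueError("subject and rater identifiers must be unique")
        self._calls = calls.astype(np.int8)

    @property
    def calls(self) -> pd.DataFrame:
        return self._calls

    @property
    def raters(self) -> list:
        return list(self._calls.columns)

    @property
    def subjects(self) -> list:
        return list(self._calls.index)

    @property
    def n_raters(self) -> int:
        return self._calls.shape[1]

    @property
    def n_subjects(self) -> int:
        return self._calls.shape[0]

    def column(self, rater) -> np.ndarray:
        return self._calls[rater].to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long format with columns rater_id, patient_id, call."""
        long = self._calls.stack().rename("call").reset_index()
        long.columns = ["patient_id", "rater_id", "call"]
        return long[["rater_id", "patient_id", "call"]]

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "RatingMatrix":
        required = {"rater_id", "patient_id", "call"}
        missing = required - set(long.columns)
        if missing:
            raise ValueError(f"ratings table lacks columns: {sorted(missing)}")
        wide = long.pivot(index="patient_id", columns="rater_id", values="call")
        return cls(wide)

    def __eq__(self, other) -> bool:
        return isinstance(other, RatingMatrix) and self._calls.equals(other._calls)


class SUSResponseSet:
    """Respondents x 10 System Usability Scale items, each on a 1-5 Likert scale."""

    N_ITEMS = 10

    def __init__(self, responses: pd.DataFrame):
        expected = [f"item_{i}" for i in range(1, self.N_ITEMS + 1)]
        if list(responses.columns) != expected:
            raise ValueError(f"SUS responses must have columns {expected}")
        values = responses.to_numpy()
        if responses.isna().any().any() or not np.isin(values, range(1, 6)).all():
            bad = responses[(responses < 1) | (responses > 5) | responses.isna()]
            row = bad.dropna(how="all").index[0]
            item = bad.loc[row].dropna().index[0]
            raise ValueError(
                f"SUS response out of the 1-5 Likert range: respondent "
                f"{row!r}, {item}"
            )
        self._responses = responses.astype(np.int64)

    @property
    def responses(self) -> pd.DataFrame:
        return self._responses

    @property
    def n_respondents(self) -> int:
        return self._responses.shape[0]

    def item_means(self) -> np.ndarray:
        return self._responses.to_numpy().mean(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, SUSResponseSet) and self._responses.equals(
            other._responses
        )
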