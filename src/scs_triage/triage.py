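"""Stage-1 triage rule engine and two-stage funnel bookkeeping.

The triage rule is a strict conjunction of declarative indicators over a
:class:`~scs_triage.records.PatientRecord`. Including indicators state a
condition that must be present (e.g. leg-dominant neuropathic pain,
DN4 > 3, NPRS leg >= 5); excluding indicators state a contraindication
that must be absent (the predicate encodes the required *absent* state,
e.g. ``widespread_pain == False`` or ``age_years > 18``). A patient is
stage-1 positive only when every indicator is satisfied.

Rules are plain data: they serialise to/from YAML, and the two shipped
profiles live under ``scs_triage/data/rules``:

``default``
    Six including and seven excluding indicators — the full rule used for
    screening an orthopaedic waiting list.
``five_indicator``
    A variant omitting the prior-back-surgery requirement, for cohorts
    where strictness of that criterion is under review.

The funnel (:func:`run_funnel`) counts patients through the two-stage
pathway: assessed -> stage-1 positive -> stage-2 pass (orthopaedic review)
-> referred to the chronic pain department. Stage 2 and referral are
external clinical decisions, supplied as labels, not computed by the rule.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .records import RULE_FIELDS, PatientRecord

__all__ = [
    "Indicator",
    "TriageRule",
    "TriageDecision",
    "FunnelSummary",
    "evaluate_stage1",
    "evaluate_boundaries",
    "run_funnel",
    "load_rule_profile",
    "rule_from_yaml",
    "rule_to_yaml",
]

Comparator = Literal["ge", "gt", "eq", "in"]

#: integer-scaled record fields (minimal satisfying value of a strict bound
#: is the next integer)
_INTEGER_FIELDS = {"dn4_score", "nprs_leg", "nprs_back"}


class FieldRef(BaseModel):
    """Reference to another record field used as a comparison threshold."""

    model_config = ConfigDict(frozen=True, extra="forbid")
    field: str

    @field_validator("field")
    @classmethod
    def _known(cls, v):
        if v not in RULE_FIELDS:
            raise ValueError(f"unknown record field {v!r}")
        return v


Threshold = Union[FieldRef, bool, int, float, str, list]


class Indicator(BaseModel):
    """A named predicate over PatientRecord fields.

    ``role`` is ``including`` (condition required present) or ``excluding``
    (contraindication required absent; the predicate states the required
    absent state). ``comparator`` is one of ``ge``/``gt``/``eq``/``in``;
    ``threshold`` is a scalar, a category list (for ``in``), or a
    ``{field: ...}`` reference to compare against another field.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    role: Literal["including", "excluding"]
    field: str
    comparator: Comparator
    threshold: Threshold

    @field_validator("field")
    @classmethod
    def _known_field(cls, v):
        if v not in RULE_FIELDS:
            raise ValueError(f"unknown record field {v!r}")
        return v

    def evaluate(self, record: PatientRecord) -> Optional[bool]:
        """True/False satisfaction, or None when the field is missing."""
        value = getattr(record, self.field)
        if value is None:
            return None
        threshold = self.threshold
        if isinstance(threshold, FieldRef):
            threshold = getattr(record, threshold.field)
            if threshold is None:
                return None
        if self.comparator == "ge":
            return bool(value >= threshold)
        if self.comparator == "gt":
            return bool(value > threshold)
        if self.comparator == "eq":
            return bool(value == threshold)
        return bool(value in threshold)  # "in"


class TriageRule(BaseModel):
    """Ordered set of indicators with a profile name and version tag."""

    model_config = ConfigDict(frozen=True)

    name: str
    version: str = "1"
    indicators: tuple[Indicator, ...]

    @field_validator("indicators")
    @classmethod
    def _named_uniquely(cls, v):
        names = [ind.name for ind in v]
        if len(set(names)) != len(names):
            raise ValueError("indicator names must be unique within a rule")
        return tuple(v)

    @property
    def including(self) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.role == "including")

    @property
    def excluding(self) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.role == "excluding")

    def without(self, indicator_name: str) -> "TriageRule":
        kept = tuple(i for i in self.indicators if i.name != indicator_name)
        if len(kept) == len(self.indicators):
            raise KeyError(indicator_name)
        return self.model_copy(update={"indicators": kept})

    def with_indicator(self, indicator: Indicator) -> "TriageRule":
        return self.model_copy(
            update={"indicators": self.indicators + (indicator,)}
        )


@dataclass(frozen=True)
class TriageDecision:
    """Stage-1 outcome for one patient.

    ``satisfied`` maps every indicator name to True/False, or None when the
    underlying field was missing; every indicator is always evaluated (no
    short-circuiting), so the vector is complete for reporting.
    """

    patient_id: str
    stage1_positive: bool
    satisfied: dict[str, Optional[bool]]
    missing_fields: tuple[str, ...]
    needs_manual_review: bool


def evaluate_stage1(
    record: PatientRecord,
    rule: TriageRule,
    missing_policy: Literal["review", "fail"] = "review",
) -> TriageDecision:
    """Apply the stage-1 rule to one patient record.

    The decision is a strict conjunction: positive only if every indicator
    is satisfied and no referenced field is missing. Under
    ``missing_policy="review"`` a record that fails *only* because of
    missing fields is negative but flagged ``needs_manual_review``; under
    ``"fail"`` it is a plain negative.
    """
    satisfied: dict[str, Optional[bool]] = {}
    missing: list[str] = []
    for indicator in rule.indicators:
        result = indicator.evaluate(record)
        satisfied[indicator.name] = result
        if result is None:
            missing.append(indicator.field)
            if isinstance(indicator.threshold, FieldRef):
                other = getattr(record, indicator.threshold.field, None)
                if other is None:
                    missing.append(indicator.threshold.field)
    positive = all(v is True for v in satisfied.values())
    fails_only_by_missing = (
        not positive
        and bool(missing)
        and all(v is not False for v in satisfied.values())
    )
    return TriageDecision(
        patient_id=record.patient_id,
        stage1_positive=positive,
        satisfied=satisfied,
        missing_fields=tuple(dict.fromkeys(missing)),
        needs_manual_review=missing_policy == "review" and fails_only_by_missing,
    )


def evaluate_boundaries(rule: TriageRule) -> pd.DataFrame:
    """Report, per numeric indicator, the minimal value that satisfies it.

    Strict bounds on integer-scaled fields resolve to the next integer
    (DN4 > 3 is first satisfied at 4); inclusive bounds are satisfied at
    the threshold itself (pain duration >= 3 months at exactly 3.0).
    Field-vs-field comparisons are satisfied at equality. Strict bounds on
    continuous fields have no attained minimum and report None.
    """
    rows = []
    for ind in rule.indicators:
        if ind.comparator not in ("ge", "gt"):
            continue
        if isinstance(ind.threshold, FieldRef):
            minimal: object = f"equality with {ind.threshold.field}"
        elif ind.comparator == "ge":
            minimal = ind.threshold
        elif ind.field in _INTEGER_FIELDS:
            minimal = int(ind.threshold) + 1
        else:
            minimal = None  # open bound on a continuous scale
        rows.append(
            {
                "indicator": ind.name,
                "field": ind.field,
                "comparator": ind.comparator,
                "threshold": (
                    ind.threshold.field
                    if isinstance(ind.threshold, FieldRef)
                    else ind.threshold
                ),
                "minimal_satisfying": minimal,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FunnelSummary:
    """Counts through the two-stage pathway plus per-patient labels."""

    assessed: int
    stage1_positive: int
    stage2_pass: int
    referred: int
    pathways: pd.DataFrame = field(repr=False, compare=False)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.assessed, self.stage1_positive, self.stage2_pass, self.referred)


def run_funnel(
    records: Sequence[PatientRecord],
    rule: TriageRule,
    stage2_labels: Iterable[bool],
    referral_labels: Iterable[bool],
    missing_policy: Literal["review", "fail"] = "review",
) -> FunnelSummary:
    """Push a cohort through the two-stage funnel.

    ``stage2_labels`` and ``referral_labels`` are the external clinical
    outcomes (latent labels in synthetic mode, a reference column in data
    mode), aligned with ``records``. Later stages are gated on earlier
    ones: a patient only passes stage 2 if stage-1 positive, and is only
    referred if they passed stage 2.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")
    stage2_labels = _as_bool_list(stage2_labels, len(records), "stage2_labels")
    referral_labels = _as_bool_list(referral_labels, len(records), "referral_labels")

    rows = []
    for rec, s2, ref in zip(records, stage2_labels, referral_labels):
        decision = evaluate_stage1(rec, rule, missing_policy)
        s1 = decision.stage1_positive
        s2_eff = s1 and s2
        ref_eff = s2_eff and ref
        pathway = (
            "referred"
            if ref_eff
            else "fast_track"
            if s2_eff
            else "stage2_review"
            if s1
            else "routine"
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "stage1_positive": s1,
                "stage2_pass": s2_eff,
                "referred": ref_eff,
                "needs_manual_review": decision.needs_manual_review,
                "pathway": pathway,
            }
        )
    pathways = pd.DataFrame(rows).set_index("patient_id")
    return FunnelSummary(
        assessed=len(records),
        stage1_positive=int(pathways["stage1_positive"].sum()),
        stage2_pass=int(pathways["stage2_pass"].sum()),
        referred=int(pathways["referred"].sum()),
        pathways=pathways,
    )


def _as_bool_list(values, n: int, name: str) -> list[bool]:
    if values is None:
        raise ValueError(f"{name} is required (data mode needs a reference column)")
    out = [bool(v) for v in values]
    if len(out) != n:
        raise ValueError(f"{name} has length {len(out)}, expected {n}")
    return out


# ---------------------------------------------------------------------------
# Serialisation


def rule_to_yaml(rule: TriageRule) -> str:
    payload = {
        "name": rule.name,
        "version": rule.version,
        "indicators": [
            {
                "name": i.name,
                "role": i.role,
                "field": i.field,
                "comparator": i.comparator,
                "threshold": (
                    {"field": i.threshold.field}
                    if isinstance(i.threshold, FieldRef)
                    else i.threshold
                ),
            }
            for i in rule.indicators
        ],
    }
    return yaml.safe_dump(payload, sort_keys=False)


def rule_from_yaml(text: str) -> TriageRule:
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict) or "indicators" not in payload:
        raise ValueError("rule YAML must be a mapping with an 'indicators' list")
    return TriageRule.model_validate(payload)


def load_rule_profile(name: str = "default") -> TriageRule:
    """Load one of the shipped rule profiles (``default``, ``five_indicator``)."""
    resource = importlib.resources.files("scs_triage").joinpath(
        "data", "rules", f"{name}.yaml"
    )
    try:
        text = resource.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise KeyError(f"unknown rule profile {name!r}") from None
    return rule_from_yaml(text)
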