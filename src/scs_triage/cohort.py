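"""Seeded synthetic generators: patient cohorts, rater calls, SUS responses.

The cohort generator emulates a heterogeneous orthopaedic waiting list of
chronic low-back-and-leg-pain patients. Each patient is first drawn as
latently stage-1 qualifying or not (Bernoulli with the funnel prevalence,
default 90/1025); qualifying patients get PROM values that satisfy every
indicator of the default triage rule, non-qualifying patients are drawn
from background marginals and are guaranteed to violate at least one
indicator. Stage-2 pass and referral are conditional Bernoulli gates
(defaults 20/90 and 8/20) — the orthopaedic review they stand in for is a
clinical judgement that is not modelled mechanistically.

Raters are simulated with a latent-class model: each rater has a
probability of calling a truly eligible subject positive and a truly
ineligible subject negative, and calls are conditionally independent given
the latent label. SUS responses are integer Likert columns constructed to
hit per-item mean targets exactly (nearest achievable integer sum).

All generators take a mandatory seed; there is no implicit global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .records import PatientRecord, RatingMatrix, SUSResponseSet
from .triage import TriageRule, evaluate_stage1, load_rule_profile

__all__ = [
    "CohortConfig",
    "Marginals",
    "RaterModel",
    "SyntheticCohort",
    "generate_cohort",
    "simulate_ratings",
    "generate_sus_responses",
]

# funnel proportions of the two-stage screening pathway these generators
# emulate: 90/1025 assessed patients stage-1 positive, 20/90 passing the
# orthopaedic review, 8/20 referred
DEFAULT_P_STAGE1 = 90 / 1025
DEFAULT_P_STAGE2 = 20 / 90
DEFAULT_P_REFERRAL = 8 / 20


class Marginals(BaseModel):
    """Background marginal distributions for non-qualifying patients.

    PROM distributions of real waiting-list cohorts are rarely published;
    these defaults are deliberately simple and fully overridable: NPRS
    uniform-discrete on its scale, DN4 binomial(10, p) with p split by
    qualifying status, pain duration log-normal with a 24-month median,
    age normal(55, 14) truncated to [19, 95] for qualifying patients.
    """

    model_config = ConfigDict(frozen=True)

    p_prior_back_surgery: float = Field(default=0.45, ge=0, le=1)
    p_location_back: float = Field(default=0.35, ge=0, le=1)
    p_location_leg: float = Field(default=0.25, ge=0, le=1)
    dn4_p_qualifying: float = Field(default=0.65, gt=0, le=1)
    dn4_p_background: float = Field(default=0.30, ge=0, le=1)
    duration_median_months: float = Field(default=24.0, gt=0)
    duration_log_sd: float = Field(default=0.9, gt=0)
    age_mean: float = Field(default=55.0, gt=0)
    age_sd: float = Field(default=14.0, gt=0)
    p_exclusion_flag: float = Field(default=0.05, ge=0, le=1)
    p_responded_conservative: float = Field(default=0.30, ge=0, le=1)

    @model_validator(mode="after")
    def _location_simplex(self):
        if self.p_location_back + self.p_location_leg > 1:
            raise ValueError("pain-location probabilities exceed 1")
        return self


class CohortConfig(BaseModel):
    """Parameters of the synthetic waiting-list cohort.

    Defaults reproduce the screening funnel proportions
    1025 -> 90 -> 20 -> 8. The seed is mandatory.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=1025, ge=0)
    p_stage1_positive: float = Field(default=DEFAULT_P_STAGE1, ge=0, le=1)
    p_stage2_pass_given_stage1: float = Field(default=DEFAULT_P_STAGE2, ge=0, le=1)
    p_referral_given_stage2: float = Field(default=DEFAULT_P_REFERRAL, ge=0, le=1)
    dn4_missing_rate: float = Field(default=0.0, ge=0, le=1)
    marginals: Marginals = Marginals()
    seed: int


class RaterModel(BaseModel):
    """Latent-class rater: per-class probabilities of a correct call."""

    model_config = ConfigDict(frozen=True)

    rater_id: str
    p_correct_positive: float = Field(ge=0, le=1)
    p_correct_negative: float = Field(ge=0, le=1)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus latent per-patient labels.

    ``labels`` is indexed by patient_id with boolean columns
    ``stage1_qualifying``, ``stage2_pass``, ``referred`` (nested subsets).
    """

    records: list[PatientRecord]
    labels: pd.DataFrame
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.records)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a synthetic waiting-list cohort with latent funnel labels.

    Qualifying patients satisfy every indicator of the default rule by
    construction (before DN4 masking); non-qualifying patients violate at
    least one. Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    rule = load_rule_profile("default")
    m = config.marginals
    n = config.n_patients

    qualifying = rng.random(n) < config.p_stage1_positive
    stage2 = qualifying & (rng.random(n) < config.p_stage2_pass_given_stage1)
    referred = stage2 & (rng.random(n) < config.p_referral_given_stage2)
    dn4_missing = rng.random(n) < config.dn4_missing_rate

    width = max(4, len(str(max(n - 1, 0))))
    records = []
    for i in range(n):
        pid = f"P{i:0{width}d}"
        if qualifying[i]:
            fields = _draw_qualifying(rng, m)
        else:
            fields = _draw_non_qualifying(rng, m, rule)
        if dn4_missing[i]:
            fields["dn4_score"] = None
        records.append(PatientRecord(patient_id=pid, **fields))

    labels = pd.DataFrame(
        {
            "stage1_qualifying": qualifying,
            "stage2_pass": stage2,
            "referred": referred,
        },
        index=pd.Index([r.patient_id for r in records], name="patient_id"),
    )
    return SyntheticCohort(records=records, labels=labels, config=config)


def _draw_qualifying(rng: np.random.Generator, m: Marginals) -> dict:
    """Field draw conditioned on satisfying the full default rule."""
    dn4 = int(rng.binomial(10, m.dn4_p_qualifying))
    while dn4 <= 3:  # truncate to the neuropathic range
        dn4 = int(rng.binomial(10, m.dn4_p_qualifying))
    mu = log(m.duration_median_months)
    duration = float(rng.lognormal(mu, m.duration_log_sd))
    while duration < 3:
        duration = float(rng.lognormal(mu, m.duration_log_sd))
    nprs_leg = int(rng.integers(5, 11))
    nprs_back = int(rng.integers(0, nprs_leg + 1))
    age = float(rng.normal(m.age_mean, m.age_sd))
    while not 19 <= age <= 95:
        age = float(rng.normal(m.age_mean, m.age_sd))
    return {
        "prior_back_surgery": True,
        "pain_location": "leg" if rng.random() < 0.5 else "mixed",
        "dn4_score": dn4,
        "pain_duration_months": duration,
        "nprs_leg": nprs_leg,
        "nprs_back": nprs_back,
        "age_years": age,
        "absolute_contraindication": False,
        "widespread_pain": False,
        "substance_abuse": False,
        "responded_conservative": False,
        "prior_scs": False,
        "anatomic_abnormality": False,
    }


def _draw_non_qualifying(
    rng: np.random.Generator, m: Marginals, rule: TriageRule
) -> dict:
    """Background draw, re-spoiled if it accidentally satisfies the rule."""
    u = rng.random()
    location = (
        "back"
        if u < m.p_location_back
        else "leg"
        if u < m.p_location_back + m.p_location_leg
        else "mixed"
    )
    fields = {
        "prior_back_surgery": bool(rng.random() < m.p_prior_back_surgery),
        "pain_location": location,
        "dn4_score": int(rng.binomial(10, m.dn4_p_background)),
        "pain_duration_months": float(
            rng.lognormal(log(m.duration_median_months), m.duration_log_sd)
        ),
        "nprs_leg": int(rng.integers(0, 11)),
        "nprs_back": int(rng.integers(0, 11)),
        "age_years": float(np.clip(rng.normal(m.age_mean, m.age_sd), 0, 100)),
        "absolute_contraindication": bool(rng.random() < m.p_exclusion_flag),
        "widespread_pain": bool(rng.random() < m.p_exclusion_flag),
        "substance_abuse": bool(rng.random() < m.p_exclusion_flag),
        "responded_conservative": bool(
            rng.random() < m.p_responded_conservative
        ),
        "prior_scs": bool(rng.random() < m.p_exclusion_flag),
        "anatomic_abnormality": bool(rng.random() < m.p_exclusion_flag),
    }
    probe = PatientRecord(patient_id="probe", **fields)
    if evaluate_stage1(probe, rule, "fail").stage1_positive:
        spoiler = int(rng.integers(0, 4))
        if spoiler == 0:
            fields["nprs_leg"] = int(rng.integers(0, 5))
        elif spoiler == 1:
            fields["dn4_score"] = int(rng.integers(0, 4))
        elif spoiler == 2:
            fields["pain_location"] = "back"
        else:
            fields["responded_conservative"] = True
    return fields


def simulate_ratings(
    latent_labels: Sequence[bool],
    raters: Sequence[RaterModel],
    seed: int,
    subject_ids: Optional[Sequence[str]] = None,
) -> RatingMatrix:
    """Draw one binary eligibility call per (rater, subject).

    Calls are conditionally independent given the latent label: a truly
    eligible subject is called positive with the rater's
    ``p_correct_positive``, a truly ineligible one negative with
    ``p_correct_negative``.
    """
    labels = np.asarray(latent_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("at least one subject is required")
    if len(raters) == 0:
        raise ValueError("at least one rater is required")
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(labels.size)]
    if len(subject_ids) != labels.size:
        raise ValueError("subject_ids length does not match labels")

    rng = np.random.default_rng(seed)
    columns = {}
    for rater in raters:
        u = rng.random(labels.size)
        calls = np.where(
            labels, u < rater.p_correct_positive, u >= rater.p_correct_negative
        )
        columns[rater.rater_id] = calls.astype(np.int8)
    frame = pd.DataFrame(
        columns, index=pd.Index(subject_ids, name="patient_id")
    )
    return RatingMatrix(frame)


def generate_sus_responses(
    n_respondents: int,
    item_mean_targets: Sequence[float],
    seed: int,
    atol: float = 0.005,
) -> SUSResponseSet:
    """Construct integer Likert responses hitting per-item mean targets.

    For each item the nearest achievable integer column sum is used; if no
    integer sum reproduces the target mean within ``atol`` (default 0.005,
    half a unit of two-decimal printing) a ValueError names the item. With
    the sum fixed, responses are the two adjacent Likert values distributed
    to match, then shuffled per-respondent with the seeded RNG.
    """
    if n_respondents < 1:
        raise ValueError("n_respondents must be >= 1")
    targets = list(item_mean_targets)
    if len(targets) != SUSResponseSet.N_ITEMS:
        raise ValueError(f"expected {SUSResponseSet.N_ITEMS} item targets")
    rng = np.random.default_rng(seed)
    columns = {}
    for j, target in enumerate(targets, start=1):
        if not 1 <= target <= 5:
            raise ValueError(f"item_{j}: target mean {target} outside [1, 5]")
        total = int(round(target * n_respondents))
        total = min(max(total, n_respondents), 5 * n_respondents)
        if abs(total / n_respondents - target) > atol + 1e-12:
            raise ValueError(
                f"item_{j}: mean {target} not achievable with "
                f"{n_respondents} integer responses (nearest "
                f"{total / n_respondents:.4f})"
            )
        base, rem = divmod(total, n_respondents)
        column = np.full(n_respondents, base, dtype=np.int64)
        column[:rem] += 1
        rng.shuffle(column)
        columns[f"item_{j}"] = column
    frame = pd.DataFrame(
        columns, index=pd.Index([f"R{i + 1}" for i in range(n_respondents)], name="respondent_id")
    )
    return SUSResponseSet(frame)
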