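import pytest

from scs_triage.records import PatientRecord
from scs_triage.triage import load_rule_profile

#: field values satisfying every indicator of the default rule
QUALIFYING_FIELDS = dict(
    prior_back_surgery=True,
    pain_location="mixed",
    dn4_score=5,
    pain_duration_months=24.0,
    nprs_leg=7,
    nprs_back=6,
    age_years=55.0,
    absolute_contraindication=False,
    widespread_pain=False,
    substance_abuse=False,
    responded_conservative=False,
    prior_scs=False,
    anatomic_abnormality=False,
)


def make_record(patient_id="P0001", **overrides) -> PatientRecord:
    fields = {**QUALIFYING_FIELDS, **overrides}
    return PatientRecord(patient_id=patient_id, **fields)


@pytest.fixture
def qualifying_record() -> PatientRecord:
    return make_record()


@pytest.fixture(scope="session")
def default_rule():
    return load_rule_profile("default")
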