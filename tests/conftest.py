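import numpy as np
import pytest

from clinaudit import (
    Cohort,
    PatientRecord,
    default_case_study_config,
    gender_exchangeable_config,
    generate_cohort,
)


def make_record(
    patient_id,
    gender="male",
    ses="low",
    smoking=0,
    peak_flow="high",
    diseases=(),
    **features,
):
    return PatientRecord(
        patient_id=str(patient_id),
        gender=gender,
        ses=ses,
        smoking=smoking,
        peak_flow_category=peak_flow,
        questionnaire=dict(features),
        diseases=frozenset(diseases),
    )


def build_cohort(records, feature_names=None):
    if feature_names is None:
        feature_names = sorted(records[0].questionnaire) if records else []
    return Cohort(records=list(records), feature_names=list(feature_names))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_case_study_config())


@pytest.fixture(scope="session")
def exchangeable_cohort():
    return generate_cohort(gender_exchangeable_config(seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
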