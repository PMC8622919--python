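import pytest

from tacmc.cohort_io import Cohort, PatientRecord, VisitObservation


@pytest.fixture
def two_patient_cohort() -> Cohort:
    """A tiny hand-built cohort: one of each sex, one AR case."""
    p1 = PatientRecord(
        patient_id="A01",
        sex="male",
        age_years=39.0,
        genotype="*3/*3",
        acute_rejection=False,
        dgf=False,
        formulation="TD",
        visits=[
            VisitObservation(3.0, 7.6, 4.0, creatinine=134.0),
            VisitObservation(6.0, 6.0, 4.0),
            VisitObservation(8.0, 8.0, 4.0),
            VisitObservation(10.0, 4.0, 4.0),
            VisitObservation(12.0, 6.0, 4.0, creatinine=140.0),
        ],
    )
    p2 = PatientRecord(
        patient_id="A02",
        sex="female",
        age_years=52.5,
        genotype="*1/*3",
        acute_rejection=True,
        visits=[
            VisitObservation(6.5, 5.2, 5.0),
            VisitObservation(9.0, 6.5, 5.0),
            VisitObservation(11.5, 5.9, 5.0),
        ],
    )
    return Cohort(patients=[p1, p2], provenance={"source": "fixture"})
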