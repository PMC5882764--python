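import pytest

from vteram import Cohort, PatientRecord, SyntheticConfig, generate_cohort

BASELINE = dict(
    patient_id="P-001",
    age=64,
    sex="male",
    histology="adenocarcinoma",
    tnm_stage="IIIA",       # not advanced
    who_ps=0,
    bmi_ge_35=False,
    coronary_artery_disease=False,
    heart_failure=False,
    hyperlipidemia=False,
    hypertension=False,
    atrial_fibrillation=False,
    stroke=False,
    peripheral_artery_disease=False,
    diabetes=False,
    copd=False,
    asthma=False,
    chronic_kidney_disease=False,
    obesity=False,
    history_other_malignancy=False,
    personal_vte_history=False,
    recent_hospitalization=False,
    platinum_chemo=False,
    gemcitabine_chemo=False,
    anthracycline_chemo=False,
    central_venous_catheter=False,
    months_since_diagnosis=7.0,  # outside the <= 6 month window
    esa_use=False,
    platelets=250.0,
    leukocytes=8.0,
    hemoglobin=13.0,
    vte=False,
    vte_time_months=None,
    death=False,
    followup_months=12.0,
)


@pytest.fixture
def make_patient():
    """Factory for a patient with no score items firing; override via kwargs."""

    def factory(**overrides) -> PatientRecord:
        fields = {**BASELINE, **overrides}
        return PatientRecord(**fields)

    return factory


@pytest.fixture
def small_cohort(make_patient):
    return Cohort(records=[
        make_patient(patient_id="A", vte=True, vte_time_months=2.0,
                     atrial_fibrillation=True),
        make_patient(patient_id="B"),
        make_patient(patient_id="C", gemcitabine_chemo=True),
    ], provenance="fixture").validate()


@pytest.fixture(scope="session")
def synthetic_cohort_118():
    return generate_cohort(SyntheticConfig(n=118, seed=42))


@pytest.fixture(scope="session")
def synthetic_cohort_2000():
    return generate_cohort(SyntheticConfig(n=2000, seed=7))
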