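"""Score a single patient with all four VTE risk models.

Builds one ambulatory lung-cancer patient — stage IV adenocarcinoma,
recently diagnosed, on platinum chemotherapy, hypertensive and diabetic,
platelets 360e9/L — and prints each model's points, risk band and the
item-level audit trail.
"""

from vteram import PatientRecord
from vteram.scores import Ram, score_patient

patient = PatientRecord(
    patient_id="EX-001", age=67, sex="male", histology="adenocarcinoma",
    tnm_stage="IV", who_ps=1, bmi_ge_35=False,
    coronary_artery_disease=False, heart_failure=False, hyperlipidemia=False,
    hypertension=True, atrial_fibrillation=False, stroke=False,
    peripheral_artery_disease=False, diabetes=True, copd=True, asthma=False,
    chronic_kidney_disease=False, obesity=False,
    history_other_malignancy=False, personal_vte_history=False,
    recent_hospitalization=True, platinum_chemo=True, gemcitabine_chemo=False,
    anthracycline_chemo=False, central_venous_catheter=False,
    months_since_diagnosis=2.0, esa_use=False,
    platelets=360.0, leukocytes=9.5, hemoglobin=12.8,
    vte=False, followup_months=12.0,
)
patient.validate()

for model in Ram:
    score = score_patient(patient, model)
    items = ", ".join(f"{name} (+{pts})" for name, pts in score.fired_items) or "none"
    print(f"{model.value:<12} {score.points:>2} points  {score.category.value:<12} {items}")

print()
print("Each line is one risk model: its point total, the risk band that total")
print("maps to (KRS-family high risk at >= 3 points, COMPASS-CAT at >= 7), and")
print("exactly which items fired. Note platelets = 360 scores in both KRS")
print("(> 350) and COMPASS-CAT (>= 350), while hypertension + diabetes fire the")
print("5-point cardiovascular composite in COMPASS-CAT only.")
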