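"""The four additive VTE risk assessment models (RAMs).

* **KRS** (Khorana risk score): cancer site + pre-chemotherapy blood counts
  + BMI.  Lung cancer carries 1 site point, so every patient in this
  lung-cancer-only package starts at 1; high risk at >= 3 points.
* **PROTECHT**: KRS plus 1 point each for platinum- and gemcitabine-based
  chemotherapy; high risk at >= 3 points.
* **CONKO**: KRS with the BMI item replaced by WHO/ECOG performance status
  >= 2; high risk at >= 3 points.
* **COMPASS-CAT**: weighted sum over treatment, tumor, comorbidity and
  biomarker items; high risk at >= 7 points.

Threshold strictness follows the clinical definitions exactly: the
KRS family uses *strict* inequalities (platelets > 350, leukocytes > 11,
hemoglobin < 10) while the COMPASS-CAT platelet biomarker is *inclusive*
(>= 350); the BMI item is inclusive (>= 35).  The distinctions only matter
exactly at the boundary and are pinned by tests.

Every score carries its ``fired_items`` audit trail — clinical score
implementations must be inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .cohort import Cohort, PatientRecord, cardiovascular_composite, is_advanced_disease

__all__ = [
    "Ram",
    "RiskCategory",
    "RamScore",
    "score_khorana",
    "score_protecht",
    "score_conko",
    "score_compass_cat",
    "classify_risk",
    "score_all",
    "COMPASS_CAT_WEIGHTS",
]


class Ram(str, Enum):
    """The four risk assessment models."""

    KRS = "KRS"
    PROTECHT = "PROTECHT"
    CONKO = "CONKO"
    COMPASS_CAT = "COMPASS_CAT"


class RiskCategory(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


#: COMPASS-CAT item weights: anthracycline 6, time since diagnosis <= 6
#: months 4, central venous catheter 3, advanced stage 2, cardiovascular
#: composite 5, recent hospitalization 5, personal VTE history 1,
#: platelets >= 350 2.  Maximum total 28.
COMPASS_CAT_WEIGHTS: dict[str, int] = {
    "anthracycline_chemo": 6,
    "diagnosis_within_6_months": 4,
    "central_venous_catheter": 3,
    "advanced_disease": 2,
    "cardiovascular_composite": 5,
    "recent_hospitalization": 5,
    "personal_vte_history": 1,
    "platelets_ge_350": 2,
}


@dataclass(frozen=True)
class RamScore:
    """Result of applying one RAM to one patient.

    ``points`` always equals the sum over ``fired_items``; ``category`` is
    consistent with :func:`classify_risk`.
    """

    model: Ram
    points: int
    category: RiskCategory
    fired_items: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        assert self.points == sum(p for _, p in self.fired_items)


def classify_risk(model: Ram, points: int) -> RiskCategory:
    """Map a point total to the model's risk band.

    KRS keeps the original three bands (0 low, 1-2 intermediate, >= 3
    high).  PROTECHT and CONKO publish only the >= 3 high-risk threshold;
    since the lung site point makes 0 unreachable here, sub-threshold
    patients are banded intermediate and low is never emitted.
    COMPASS-CAT is two-band: >= 7 high, else low.
    """
    model = Ram(model)
    if points < 0:
        raise ValueError(f"points must be non-negative, got {points}")
    if model is Ram.COMPASS_CAT:
        return RiskCategory.HIGH if points >= 7 else RiskCategory.LOW
    if points >= 3:
        return RiskCategory.HIGH
    if model is Ram.KRS and points == 0:
        return RiskCategory.LOW
    return RiskCategory.INTERMEDIATE


def _build(model: Ram, items: list[tuple[str, int, bool]]) -> RamScore:
    fired = tuple((name, pts) for name, pts, on in items if on)
    points = sum(p for _, p in fired)
    return RamScore(model=model, points=points,
                    category=classify_risk(model, points), fired_items=fired)


def _krs_blood_items(patient: PatientRecord) -> list[tuple[str, int, bool]]:
    return [
        ("lung_cancer_site", 1, True),  # site point: always 1 for this lung-only package
        ("platelets_gt_350", 1, patient.platelets > 350),
        ("leukocytes_gt_11", 1, patient.leukocytes > 11),
        ("hemoglobin_lt_10_or_esa", 1, patient.hemoglobin < 10 or patient.esa_use),
    ]


def score_khorana(patient: PatientRecord) -> RamScore:
    """Khorana risk score: site + platelets > 350 + leukocytes > 11 +
    (hemoglobin < 10 g/dL or ESA use) + BMI >= 35, 1 point each."""
    items = _krs_blood_items(patient) + [("bmi_ge_35", 1, patient.bmi_ge_35)]
    return _build(Ram.KRS, items)


def score_protecht(patient: PatientRecord) -> RamScore:
    """PROTECHT score: KRS plus 1 point each for platinum- and
    gemcitabine-based chemotherapy."""
    krs = score_khorana(patient)
    items = [(name, pts, True) for name, pts in krs.fired_items]
    items += [
        ("platinum_chemo", 1, patient.platinum_chemo),
        ("gemcitabine_chemo", 1, patient.gemcitabine_chemo),
    ]
    return _build(Ram.PROTECHT, items)


def score_conko(patient: PatientRecord) -> RamScore:
    """CONKO score: KRS with the BMI item replaced by WHO/ECOG performance
    status >= 2 (1 point)."""
    items = _krs_blood_items(patient) + [("who_ps_ge_2", 1, patient.who_ps >= 2)]
    return _build(Ram.CONKO, items)


def score_compass_cat(patient: PatientRecord) -> RamScore:
    """COMPASS-CAT score with the weights in :data:`COMPASS_CAT_WEIGHTS`.

    The advanced-stage and cardiovascular items are derived from the
    patient's stage and comorbidity flags (see
    :func:`vteram.cohort.is_advanced_disease` and
    :func:`vteram.cohort.cardiovascular_composite`).
    """
    w = COMPASS_CAT_WEIGHTS
    items = [
        ("anthracycline_chemo", w["anthracycline_chemo"], patient.anthracycline_chemo),
        ("diagnosis_within_6_months", w["diagnosis_within_6_months"],
         patient.months_since_diagnosis <= 6),
        ("central_venous_catheter", w["central_venous_catheter"],
         patient.central_venous_catheter),
        ("advanced_disease", w["advanced_disease"], is_advanced_disease(patient)),
        ("cardiovascular_composite", w["cardiovascular_composite"],
         cardiovascular_composite(patient)),
        ("recent_hospitalization", w["recent_hospitalization"],
         patient.recent_hospitalization),
        ("personal_vte_history", w["personal_vte_history"], patient.personal_vte_history),
        ("platelets_ge_350", w["platelets_ge_350"], patient.platelets >= 350),
    ]
    return _build(Ram.COMPASS_CAT, items)


_SCORERS = {
    Ram.KRS: score_khorana,
    Ram.PROTECHT: score_protecht,
    Ram.CONKO: score_conko,
    Ram.COMPASS_CAT: score_compass_cat,
}


def score_patient(patient: PatientRecord, model: Ram) -> RamScore:
    """Apply one named RAM to one patient."""
    return _SCORERS[Ram(model)](patient)


def score_all(cohort: Cohort, models: tuple[Ram, ...] = tuple(Ram)) -> pd.DataFrame:
    """Score every patient with every requested model.

    Returns a tidy frame with one row per patient x model and columns
    ``patient_id, model, points, category, fired_items`` (the audit trail
    serialized as semicolon-joined ``item=points`` tokens).
    """
    rows = []
    for record in cohort:
        for model in models:
            try:
                score = _SCORERS[Ram(model)](record)
            except Exception as exc:  # pragma: no cover - defensive context
                raise type(exc)(f"patient {record.patient_id!r}: {exc}") from exc
            rows.append({
                "patient_id": record.patient_id,
                "model": score.model.value,
                "points": score.points,
                "category": score.category.value,
                "fired_items": ";".join(f"{n}={p}" for n, p in score.fired_items),
            })
    return pd.DataFrame(rows, columns=["patient_id", "model", "points", "category", "fired_items"])
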