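"""Patient-level cohort data model for ambulatory lung-cancer VTE studies.

A :class:`PatientRecord` carries the demographics, comorbidity flags, TNM
stage, treatment flags, pre-chemotherapy blood counts and the VTE outcome
needed by the four risk assessment models.  A :class:`Cohort` is an ordered,
validated collection of records with a CSV round trip.

Conventions
-----------
* Booleans are serialized strictly as ``0``/``1``; ``true``/``false`` are
  accepted case-insensitively on input.
* TNM stage codes are normalized to upper case without spaces
  (``"IIIb"`` -> ``"IIIB"``).
* Mandatory fields may not be missing: a row with a missing mandatory field
  is rejected with a diagnostic naming the patient and the field, never
  silently imputed (imputation would corrupt score counts downstream).
* ``obesity`` is defined as BMI >= 35 kg/m^2 and must agree with
  ``bmi_ge_35``; the same threshold plays both the body-habitus role in the
  Khorana-family scores and the cardiovascular-predictor role in
  COMPASS-CAT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "is_advanced_disease",
    "cardiovascular_composite",
    "SEXES",
    "HISTOLOGIES",
    "TNM_STAGES",
    "ADVANCED_STAGES",
    "CARDIOVASCULAR_PREDICTORS",
    "CSV_COLUMNS",
]

SEXES = ("male", "female")
HISTOLOGIES = ("squamous", "adenocarcinoma", "small_cell", "adenoid_cystic", "nos")
#: TNM 7th-edition stage codes used for lung cancer in this package.
TNM_STAGES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV")
#: Stages counted as advanced disease.
ADVANCED_STAGES = frozenset({"IIIB", "IV"})

#: The seven predictors of the COMPASS-CAT cardiovascular composite; the
#: composite fires when at least two are present.
CARDIOVASCULAR_PREDICTORS = (
    "peripheral_artery_disease",
    "stroke",
    "coronary_artery_disease",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "obesity",
)


class CohortSchemaError(ValueError):
    """The CSV is missing a mandatory column or is otherwise malformed."""


class CohortValidationError(ValueError):
    """A record or cohort violates a data-model invariant."""


@dataclass
class PatientRecord:
    """One patient's covariates, treatment, blood counts and outcome.

    Blood counts are in the units the scores are defined on: platelets and
    leukocytes in 10^9/L, hemoglobin in g/dL.  ``vte_time_months`` is only
    present when ``vte`` is true.
    """

    patient_id: str
    age: int
    sex: str
    histology: str
    tnm_stage: str
    who_ps: int
    bmi_ge_35: bool
    coronary_artery_disease: bool
    heart_failure: bool
    hyperlipidemia: bool
    hypertension: bool
    atrial_fibrillation: bool
    stroke: bool
    peripheral_artery_disease: bool
    diabetes: bool
    copd: bool
    asthma: bool
    chronic_kidney_disease: bool
    obesity: bool
    history_other_malignancy: bool
    personal_vte_history: bool
    recent_hospitalization: bool
    platinum_chemo: bool
    gemcitabine_chemo: bool
    anthracycline_chemo: bool
    central_venous_catheter: bool
    months_since_diagnosis: float
    esa_use: bool
    platelets: float
    leukocytes: float
    hemoglobin: float
    vte: bool
    vte_time_months: Optional[float] = None
    death: bool = False
    followup_months: float = 1.0

    def __post_init__(self) -> None:
        self.tnm_stage = str(self.tnm_stage).replace(" ", "").upper()

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` on any invariant violation."""
        pid = self.patient_id
        if not pid:
            raise CohortValidationError("patient_id must be a non-empty string")
        if self.age < 18:
            raise CohortValidationError(f"{pid}: age must be >= 18, got {self.age}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"{pid}: sex must be one of {SEXES}, got {self.sex!r}")
        if self.histology not in HISTOLOGIES:
            raise CohortValidationError(
                f"{pid}: histology must be one of {HISTOLOGIES}, got {self.histology!r}"
            )
        if self.tnm_stage not in TNM_STAGES:
            raise CohortValidationError(
                f"{pid}: tnm_stage must be one of {TNM_STAGES}, got {self.tnm_stage!r}"
            )
        if self.who_ps not in (0, 1, 2, 3, 4):
            raise CohortValidationError(f"{pid}: who_ps must be 0-4, got {self.who_ps}")
        for name in ("platelets", "leukocytes", "hemoglobin"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise CohortValidationError(f"{pid}: {name} must be a positive real, got {value}")
        if self.months_since_diagnosis < 0:
            raise CohortValidationError(
                f"{pid}: months_since_diagnosis must be non-negative, "
                f"got {self.months_since_diagnosis}"
            )
        if self.bmi_ge_35 != self.obesity:
            raise CohortValidationError(
                f"{pid}: bmi_ge_35 and obesity encode the same BMI >= 35 kg/m^2 "
                f"threshold and must agree ({self.bmi_ge_35} vs {self.obesity})"
            )
        if not self.vte and self.vte_time_months is not None:
            raise CohortValidationError(
                f"{pid}: vte_time_months must be absent when vte is false"
            )
        if self.vte_time_months is not None and self.vte_time_months < 0:
            raise CohortValidationError(f"{pid}: vte_time_months must be non-negative")
        if not (self.followup_months > 0):
            raise CohortValidationError(f"{pid}: followup_months must be positive")


@dataclass
class Cohort:
    """Ordered collection of validated :class:`PatientRecord` objects."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, index):
        return self.records[index]

    def validate(self) -> "Cohort":
        seen: set[str] = set()
        for record in self.records:
            record.validate()
            if record.patient_id in seen:
                raise CohortValidationError(
                    f"duplicate patient_id {record.patient_id!r} in cohort"
                )
            seen.add(record.patient_id)
        return self

    def require_nonempty(self) -> "Cohort":
        if not self.records:
            raise CohortValidationError("cohort is empty; analysis needs >= 1 record")
        return self


# --- composite field derivations -------------------------------------------

def is_advanced_disease(patient: PatientRecord) -> bool:
    """True iff the tumor stage is IIIB or IV (TNM 7th edition)."""
    return patient.tnm_stage in ADVANCED_STAGES


def cardiovascular_composite(patient: PatientRecord) -> bool:
    """COMPASS-CAT cardiovascular risk composite.

    Fires when at least two of: peripheral artery disease, ischemic stroke,
    coronary artery disease, hypertension, hyperlipidemia, diabetes, obesity.
    """
    return sum(bool(getattr(patient, name)) for name in CARDIOVASCULAR_PREDICTORS) >= 2


# --- CSV serialization ------------------------------------------------------

_BOOL_FIELDS = frozenset(
    f.name for f in dc_fields(PatientRecord) if f.type == "bool"
)
_INT_FIELDS = frozenset({"age", "who_ps"})
_FLOAT_FIELDS = frozenset(
    {"months_since_diagnosis", "platelets", "leukocytes", "hemoglobin", "followup_months"}
)
_OPTIONAL_FLOAT_FIELDS = frozenset({"vte_time_months"})

#: Canonical column order of the cohort CSV (the PatientRecord field order).
CSV_COLUMNS: tuple[str, ...] = tuple(f.name for f in dc_fields(PatientRecord))

_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def _parse_cell(name: str, raw: str, pid: str):
    raw = raw.strip()
    try:
        if name in _BOOL_FIELDS:
            low = raw.lower()
            if low in _TRUE_TOKENS:
                return True
            if low in _FALSE_TOKENS:
                return False
            raise ValueError(f"expected 0/1/true/false, got {raw!r}")
        if name in _INT_FIELDS:
            return int(raw)
        if name in _FLOAT_FIELDS:
            return float(raw)
        if name in _OPTIONAL_FLOAT_FIELDS:
            return float(raw) if raw != "" else None
        return raw
    except ValueError as exc:
        raise CohortValidationError(
            f"patient {pid!r}: cannot parse field {name!r}: {exc}"
        ) from None


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read and validate a cohort from CSV.

    The file must have a header with the canonical column names
    (:data:`CSV_COLUMNS`); unknown columns are preserved on disk but ignored
    here.  Errors name the offending column or patient/field.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records = []
    for _, row in frame.iterrows():
        pid = row["patient_id"]
        for name in CSV_COLUMNS:
            if name not in _OPTIONAL_FLOAT_FIELDS and row[name].strip() == "":
                raise CohortValidationError(
                    f"patient {pid!r}: mandatory field {name!r} is missing"
                )
        kwargs = {name: _parse_cell(name, row[name], pid) for name in CSV_COLUMNS}
        records.append(PatientRecord(**kwargs))
    return Cohort(records=records, provenance=str(path)).validate()


def _format_cell(name: str, value) -> str:
    if name in _BOOL_FIELDS:
        return "1" if value else "0"
    if name in _OPTIONAL_FLOAT_FIELDS:
        return "" if value is None else repr(float(value))
    if name in _FLOAT_FIELDS:
        return repr(float(value))
    return str(value)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write a validated cohort to CSV in canonical column order."""
    cohort.validate()
    path = Path(path)
    rows = [
        {name: _format_cell(name, getattr(record, name)) for name in CSV_COLUMNS}
        for record in cohort
    ]
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False)
    return path


def cohort_from_records(records: Iterable[PatientRecord], provenance: str = "") -> Cohort:
    """Build and validate a cohort from an iterable of records."""
    return Cohort(records=list(records), provenance=provenance).validate()
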