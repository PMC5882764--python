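"""Seeded synthetic lung-cancer cohorts with a logistic VTE outcome model.

The generator emulates a single-center ambulatory lung-cancer cohort:
covariates are drawn independently from configured marginal prevalences
(defaults match a 118-patient reference population: 58% male, 11% atrial
fibrillation, 13% chronic kidney disease, 81% platinum- and 21%
gemcitabine-based chemotherapy, 56% recently hospitalized, 34% with
platelets above 350e9/L, ...), the TNM stage is drawn categorically and
advanced disease is *derived* from it, blood counts are drawn from
continuous distributions calibrated so their threshold-crossing
probabilities match the configured prevalences, and the VTE outcome is
drawn from a logistic model

    logit P(VTE) = beta0 + sum_f ln(OR_f) * 1[f active]

whose active factors default to a high COMPASS-CAT score (OR 8.73),
gemcitabine chemotherapy (OR 3.37) and atrial fibrillation (OR 7.19).
The high-COMPASS-CAT indicator is computed from the patient's own
generated covariates via :func:`vteram.scores.score_compass_cat`, so the
outcome model and the score being validated share a causal pathway, as
they do in real cohorts.  The intercept ``beta0`` is calibrated by
bisection so the expected event rate equals ``target_vte_rate``
(default 16.9%).

Reproducibility contract: a single ``numpy.random.default_rng(seed)``
stream drives all draws; fields are drawn vectorized over patients in
the fixed order documented in :func:`generate_cohort`.  The same config
and seed always give the identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .cohort import Cohort, PatientRecord
from .scores import score_compass_cat

__all__ = ["SyntheticConfig", "generate_cohort", "calibrate_intercept"]

#: TNM stage counts of the reference population (IA..IV out of 118).
DEFAULT_STAGE_COUNTS: dict[str, int] = {
    "IA": 1, "IB": 4, "IIA": 4, "IIB": 6, "IIIA": 16, "IIIB": 15, "IV": 72,
}

#: Histology counts of the reference population.
DEFAULT_HISTOLOGY_COUNTS: dict[str, int] = {
    "squamous": 37, "adenocarcinoma": 57, "small_cell": 21,
    "adenoid_cystic": 1, "nos": 2,
}

DEFAULT_PREVALENCES: dict[str, float] = {
    "male": 68 / 118,
    "who_ps_ge_2": 18 / 118,
    "bmi_ge_35": 6 / 118,
    "coronary_artery_disease": 32 / 118,
    "heart_failure": 5 / 118,
    "hyperlipidemia": 54 / 118,
    "hypertension": 71 / 118,
    "atrial_fibrillation": 13 / 118,
    "stroke": 2 / 118,
    # no reference-population count exists; 8% is typical of a heavy-smoker
    # oncology clinic and keeps the cardiovascular composite realistic
    "peripheral_artery_disease": 0.08,
    "diabetes": 24 / 118,
    "copd": 25 / 118,
    "asthma": 6 / 118,
    "chronic_kidney_disease": 15 / 118,
    "history_other_malignancy": 24 / 118,
    "personal_vte_history": 5 / 118,
    "recent_hospitalization": 66 / 118,
    "platinum_chemo": 96 / 118,
    "gemcitabine_chemo": 25 / 118,
    "anthracycline_chemo": 0.0,   # none administered in the reference setting
    "central_venous_catheter": 7 / 118,
    "esa_use": 0.0,               # ESAs not administered
    "platelets_gt_350": 40 / 118,
    "leukocytes_gt_11": 26 / 118,
    "hemoglobin_lt_10": 4 / 118,
    "death": 76 / 118,
}

DEFAULT_EFFECT_ORS: dict[str, float] = {
    "high_compass_cat": 8.73,
    "gemcitabine_chemo": 3.37,
    "atrial_fibrillation": 7.19,
}

# log-scale spreads of the blood-count distributions (platelets and
# leukocytes log-normal; hemoglobin normal with sd in g/dL).  The location
# parameters are solved from the configured threshold-crossing
# probabilities, so these shapes only set realistic dispersion.
_PLATELET_SIGMA = 0.35
_LEUKOCYTE_SIGMA = 0.30
_HEMOGLOBIN_SD = 1.6

_CALIBRATION_SEED = 915_587_401   # fixed internal stream for intercept bisection
_CALIBRATION_N = 200_000


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    ``prevalences`` maps covariate names to marginal probabilities;
    ``effect_ors`` maps active outcome factors to their odds ratios;
    ``target_vte_rate`` is the marginal event rate the intercept is
    calibrated to.  Omitted keys keep the reference-population defaults.
    """

    n: int = 118
    seed: int = 0
    prevalences: dict[str, float] = field(default_factory=dict)
    effect_ors: dict[str, float] = field(default_factory=dict)
    target_vte_rate: float = 20 / 118
    stage_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGE_COUNTS))
    histology_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_COUNTS))
    max_months_since_diagnosis: float = 12.0
    vte_time_median_months: float = 2.5

    def resolved_prevalences(self) -> dict[str, float]:
        merged = {**DEFAULT_PREVALENCES, **self.prevalences}
        unknown = set(self.prevalences) - set(DEFAULT_PREVALENCES)
        if unknown:
            raise ValueError(f"unknown prevalence keys: {sorted(unknown)}")
        for name, p in merged.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence {name}={p} outside [0, 1]")
        return merged

    def resolved_effect_ors(self) -> dict[str, float]:
        merged = {**DEFAULT_EFFECT_ORS, **self.effect_ors}
        for name, value in merged.items():
            if not value > 0:
                raise ValueError(f"effect OR {name}={value} must be positive")
        return merged

    def validate(self) -> "SyntheticConfig":
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (0.0 < self.target_vte_rate < 1.0):
            raise ValueError(
                f"target_vte_rate must lie strictly inside (0, 1); "
                f"{self.target_vte_rate} is not achievable by a logistic model"
            )
        self.resolved_prevalences()
        self.resolved_effect_ors()
        return self


def _threshold_lognormal(rng: np.random.Generator, n: int, threshold: float,
                         p_exceed: float, sigma: float) -> np.ndarray:
    """Log-normal draws with P(X > threshold) = p_exceed."""
    mu = math.log(threshold) - sigma * norm.ppf(1.0 - min(max(p_exceed, 1e-12), 1 - 1e-12))
    return np.exp(rng.normal(mu, sigma, size=n))


def _covariate_frame(rng: np.random.Generator, config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Draw all covariates for ``config.n`` patients.

    Draw order (one vectorized draw per line, all from the same stream):
    age, sex, histology, stage, who_ps, bmi/obesity, the ten comorbidity
    flags in record order, malignancy history, VTE history, recent
    hospitalization, the three chemotherapy flags, catheter, months since
    diagnosis, ESA use, platelets, leukocytes, hemoglobin.
    """
    n = config.n
    prev = config.resolved_prevalences()

    def bern(p: float) -> np.ndarray:
        return rng.random(n) < p

    cov: dict[str, np.ndarray] = {}
    cov["age"] = np.clip(np.rint(rng.normal(64.0, 10.0, size=n)), 39, 83).astype(int)
    cov["sex"] = np.where(bern(prev["male"]), "male", "female")

    hist_names = list(config.histology_counts)
    hist_p = np.array([config.histology_counts[k] for k in hist_names], dtype=float)
    cov["histology"] = rng.choice(hist_names, size=n, p=hist_p / hist_p.sum())

    stage_names = list(config.stage_counts)
    stage_p = np.array([config.stage_counts[k] for k in stage_names], dtype=float)
    cov["tnm_stage"] = rng.choice(stage_names, size=n, p=stage_p / stage_p.sum())

    # performance status: >= 2 with the configured prevalence, then split
    # 0/1 evenly below and 2 (vast majority) vs 3 above
    ps_high = bern(prev["who_ps_ge_2"])
    ps_low_draw = rng.integers(0, 2, size=n)
    ps_high_draw = np.where(rng.random(n) < 0.85, 2, 3)
    cov["who_ps"] = np.where(ps_high, ps_high_draw, ps_low_draw).astype(int)

    cov["bmi_ge_35"] = bern(prev["bmi_ge_35"])
    cov["obesity"] = cov["bmi_ge_35"]  # same BMI >= 35 threshold, kept identical
    for name in ("coronary_artery_disease", "heart_failure", "hyperlipidemia",
                 "hypertension", "atrial_fibrillation", "stroke",
                 "peripheral_artery_disease", "diabetes", "copd", "asthma",
                 "chronic_kidney_disease", "history_other_malignancy",
                 "personal_vte_history", "recent_hospitalization",
                 "platinum_chemo", "gemcitabine_chemo", "anthracycline_chemo",
                 "central_venous_catheter"):
        cov[name] = bern(prev[name])
    cov["months_since_diagnosis"] = config.max_months_since_diagnosis * (
        1.0 - rng.random(n))  # uniform on (0, max]
    cov["esa_use"] = bern(prev["esa_use"])
    cov["platelets"] = _threshold_lognormal(rng, n, 350.0, prev["platelets_gt_350"],
                                            _PLATELET_SIGMA)
    cov["leukocytes"] = _threshold_lognormal(rng, n, 11.0, prev["leukocytes_gt_11"],
                                             _LEUKOCYTE_SIGMA)
    hb_mean = 10.0 - _HEMOGLOBIN_SD * norm.ppf(prev["hemoglobin_lt_10"])
    cov["hemoglobin"] = np.maximum(rng.normal(hb_mean, _HEMOGLOBIN_SD, size=n), 0.5)
    return cov


def _records_without_outcome(cov: dict[str, np.ndarray], n: int) -> list[PatientRecord]:
    records = []
    for i in range(n):
        records.append(PatientRecord(
            patient_id=f"SYN-{i + 1:06d}",
            age=int(cov["age"][i]),
            sex=str(cov["sex"][i]),
            histology=str(cov["histology"][i]),
            tnm_stage=str(cov["tnm_stage"][i]),
            who_ps=int(cov["who_ps"][i]),
            bmi_ge_35=bool(cov["bmi_ge_35"][i]),
            coronary_artery_disease=bool(cov["coronary_artery_disease"][i]),
            heart_failure=bool(cov["heart_failure"][i]),
            hyperlipidemia=bool(cov["hyperlipidemia"][i]),
            hypertension=bool(cov["hypertension"][i]),
            atrial_fibrillation=bool(cov["atrial_fibrillation"][i]),
            stroke=bool(cov["stroke"][i]),
            peripheral_artery_disease=bool(cov["peripheral_artery_disease"][i]),
            diabetes=bool(cov["diabetes"][i]),
            copd=bool(cov["copd"][i]),
            asthma=bool(cov["asthma"][i]),
            chronic_kidney_disease=bool(cov["chronic_kidney_disease"][i]),
            obesity=bool(cov["obesity"][i]),
            history_other_malignancy=bool(cov["history_other_malignancy"][i]),
            personal_vte_history=bool(cov["personal_vte_history"][i]),
            recent_hospitalization=bool(cov["recent_hospitalization"][i]),
            platinum_chemo=bool(cov["platinum_chemo"][i]),
            gemcitabine_chemo=bool(cov["gemcitabine_chemo"][i]),
            anthracycline_chemo=bool(cov["anthracycline_chemo"][i]),
            central_venous_catheter=bool(cov["central_venous_catheter"][i]),
            months_since_diagnosis=float(cov["months_since_diagnosis"][i]),
            esa_use=bool(cov["esa_use"][i]),
            platelets=float(cov["platelets"][i]),
            leukocytes=float(cov["leukocytes"][i]),
            hemoglobin=float(cov["hemoglobin"][i]),
            vte=False,
        ))
    return records


def _factor_indicator(name: str, record: PatientRecord) -> bool:
    if name == "high_compass_cat":
        return score_compass_cat(record).points >= 7
    return bool(getattr(record, name))


def _linear_offsets(records: list[PatientRecord], effect_ors: dict[str, float]) -> np.ndarray:
    offsets = np.zeros(len(records))
    for name, or_value in effect_ors.items():
        log_or = math.log(or_value)
        offsets += log_or * np.array(
            [_factor_indicator(name, r) for r in records], dtype=float)
    return offsets


_calibration_memo: dict[str, float] = {}


def _calibration_key(config: SyntheticConfig) -> str:
    # beta0 depends on everything except n, seed and the outcome-time settings
    return repr((sorted(config.resolved_prevalences().items()),
                 sorted(config.resolved_effect_ors().items()),
                 config.target_vte_rate,
                 sorted(config.stage_counts.items()),
                 sorted(config.histology_counts.items()),
                 config.max_months_since_diagnosis))


def calibrate_intercept(config: SyntheticConfig) -> float:
    """Intercept beta0 making the expected VTE rate equal the target.

    When every patient shares the same linear-predictor offset the
    closed form ``logit(target) - offset`` is returned exactly.
    Otherwise beta0 is found by bisection against a Monte-Carlo covariate
    sample drawn from a fixed internal stream, to a rate tolerance well
    below 1e-4 (the achieved-rate function is strictly monotone in
    beta0).
    """
    config.validate()
    effect_ors = config.resolved_effect_ors()
    if all(abs(v - 1.0) < 1e-15 for v in effect_ors.values()):
        return float(logit(config.target_vte_rate))
    key = _calibration_key(config)
    if key in _calibration_memo:
        return _calibration_memo[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    cal_config = replace(config, n=_CALIBRATION_N)
    cov = _covariate_frame(rng, cal_config)
    records = _records_without_outcome(cov, _CALIBRATION_N)
    offsets = _linear_offsets(records, effect_ors)
    if np.ptp(offsets) == 0.0:
        return float(logit(config.target_vte_rate) - offsets[0])

    def achieved(beta0: float) -> float:
        return float(np.mean(expit(beta0 + offsets)))

    lo, hi = -40.0, 40.0
    target = config.target_vte_rate
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if achieved(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    _calibration_memo[key] = 0.5 * (lo + hi)
    return _calibration_memo[key]


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a validated synthetic cohort, deterministic given the seed.

    Draw order: the covariates of :func:`_covariate_frame`, then the VTE
    indicator, then the follow-up time, the VTE event time (exponential
    with the configured median, truncated at follow-up) and the death
    indicator.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    if n == 0:
        return Cohort(records=[], provenance=f"synthetic(seed={config.seed}, n=0)")
    cov = _covariate_frame(rng, config)
    records = _records_without_outcome(cov, n)

    beta0 = calibrate_intercept(config)
    probs = expit(beta0 + _linear_offsets(records, config.resolved_effect_ors()))
    vte = rng.random(n) < probs
    followup = rng.uniform(1.0, 24.0, size=n)
    scale = config.vte_time_median_months / math.log(2.0)
    vte_time = np.minimum(rng.exponential(scale, size=n), followup)
    death = rng.random(n) < config.resolved_prevalences()["death"]

    for i, record in enumerate(records):
        record.vte = bool(vte[i])
        record.vte_time_months = float(vte_time[i]) if vte[i] else None
        record.followup_months = float(followup[i])
        record.death = bool(death[i])
    return Cohort(
        records=records,
        provenance=f"synthetic(seed={config.seed}, n={n})",
    ).validate()
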