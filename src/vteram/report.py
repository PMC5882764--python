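"""End-to-end analysis: score -> stratify -> validate -> regress -> ROC.

:func:`run_analysis` reproduces the shape of a clinical validation study
on any input cohort: per-model risk stratification tables with VTE rates,
diagnostic metrics of each high-risk split, a univariate odds-ratio
screen, the screen-selected multivariate logistic model, and the ROC
analysis (AUC/C statistic, Youden cutoff) of the COMPASS-CAT point score.
All numbers are stored at full precision; the text rendering applies the
half-up percent rounding of printed clinical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Optional

import numpy as np

from . import __version__
from .cohort import Cohort, PatientRecord, is_advanced_disease
from .scores import Ram, RiskCategory, score_compass_cat, score_patient
from .stats import (
    LogisticFit,
    RocCurve,
    build_two_by_two,
    diagnostic_metrics,
    multivariate_model,
    optimal_cutoff,
    percent,
    roc_curve,
    univariate_screen,
)

__all__ = ["AnalysisOptions", "AnalysisReport", "run_analysis", "default_factors"]

log = logging.getLogger("vteram")


def default_factors() -> list[tuple[str, Callable[[PatientRecord], bool]]]:
    """The default univariate screen: the factors a VTE validation study
    examines — the high COMPASS-CAT group plus the treatment and
    comorbidity candidates."""
    return [
        ("high_compass_cat", lambda r: score_compass_cat(r).points >= 7),
        ("gemcitabine_chemo", lambda r: r.gemcitabine_chemo),
        ("atrial_fibrillation", lambda r: r.atrial_fibrillation),
        ("recent_hospitalization", lambda r: r.recent_hospitalization),
        ("chronic_kidney_disease", lambda r: r.chronic_kidney_disease),
        ("advanced_disease", is_advanced_disease),
    ]


@dataclass
class AnalysisOptions:
    alpha_in: float = 0.01
    factors: Optional[list[tuple[str, Callable[[PatientRecord], bool]]]] = None
    seed: Optional[int] = None   # recorded in metadata only; the analysis is deterministic

    def config_hash(self) -> str:
        names = [n for n, _ in (self.factors or default_factors())]
        payload = json.dumps({"alpha_in": self.alpha_in, "factors": names, "seed": self.seed})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Full analysis output; ``to_dict``/``to_json`` are stable and
    byte-identical across reruns apart from the timestamp field."""

    n: int
    vte_count: int
    vte_rate: float
    stratification: dict[str, list[dict]]
    diagnostics: dict[str, dict]
    screen_table: list[dict]
    multivariate: Optional[dict]
    roc: dict
    flags: list[str]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cohort": {"n": self.n, "vte_count": self.vte_count, "vte_rate": self.vte_rate},
            "stratification": self.stratification,
            "diagnostics": self.diagnostics,
            "univariate_screen": self.screen_table,
            "multivariate": self.multivariate,
            "roc": self.roc,
            "flags": self.flags,
            "metadata": self.metadata,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=_jsonify)

    def to_text(self) -> str:
        lines = [
            f"Cohort: n={self.n}, VTE events={self.vte_count} "
            f"({percent(self.vte_rate, 1)}%)",
            "",
            "Risk stratification (per model)",
        ]
        for model, rows in self.stratification.items():
            lines.append(f"  {model}:")
            for row in rows:
                rate = percent(row["vte_rate"], 1) if row["n"] else 0.0
                lines.append(
                    f"    {row['category']:<13} n={row['n']:<5} VTE={row['vte']:<4} "
                    f"rate={rate}%"
                )
        lines += ["", "Diagnostic metrics of each high-risk split (%)"]
        for model, metrics in self.diagnostics.items():
            parts = ", ".join(
                f"{k}={'NA' if v is None else v}" for k, v in metrics["percent"].items()
            )
            lines.append(f"  {model}: {parts}  (C statistic {metrics['c_statistic']:.2f})")
        lines += ["", "Univariate screen (OR, 95% CI, chi-square p)"]
        for row in self.screen_table:
            if row["estimable"]:
                lines.append(
                    f"  {row['factor']:<24} OR {row['or']:.2f} "
                    f"({row['ci_low']:.2f}-{row['ci_high']:.2f})  p={row['p']:.4f}"
                )
            else:
                lines.append(f"  {row['factor']:<24} {row['note'] or 'non-estimable'}")
        lines.append("")
        if self.multivariate is None:
            lines.append("Multivariate model: not fitted (see flags)")
        else:
            lines.append("Multivariate logistic model (OR, 95% CI, Wald p)")
            for term in self.multivariate["terms"]:
                if term["term"] == "intercept":
                    continue
                lines.append(
                    f"  {term['term']:<24} OR {term['or']:.2f} "
                    f"({term['ci_low']:.2f}-{term['ci_high']:.2f})  p={term['p']:.4f}"
                )
        lines += [
            "",
            (
                f"COMPASS-CAT ROC: AUC {self.roc['auc']:.3f} "
                f"(SE {self.roc['auc_se']:.3f}, 95% CI {self.roc['auc_ci'][0]:.3f}-"
                f"{self.roc['auc_ci'][1]:.3f}); "
                f"optimal cutoff {self.roc['cutoff']:g} points "
                f"(sensitivity {percent(self.roc['cutoff_sensitivity'])}%, "
                f"specificity {percent(self.roc['cutoff_specificity'])}%)"
            ),
        ]
        if self.flags:
            lines += ["", "Flags:"] + [f"  - {f}" for f in self.flags]
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# categories each model can emit (PROTECHT/CONKO never emit low because of
# the unconditional lung-site point; COMPASS-CAT is two-band)
_MODEL_CATEGORIES = {
    Ram.KRS: (RiskCategory.LOW, RiskCategory.INTERMEDIATE, RiskCategory.HIGH),
    Ram.PROTECHT: (RiskCategory.INTERMEDIATE, RiskCategory.HIGH),
    Ram.CONKO: (RiskCategory.INTERMEDIATE, RiskCategory.HIGH),
    Ram.COMPASS_CAT: (RiskCategory.LOW, RiskCategory.HIGH),
}


def _stratify(cohort: Cohort, model: Ram) -> list[dict]:
    rows = []
    scored = [(score_patient(r, model), r.vte) for r in cohort]
    for category in _MODEL_CATEGORIES[model]:
        members = [(s, v) for s, v in scored if s.category is category]
        n = len(members)
        vte = sum(v for _, v in members)
        rows.append({
            "category": category.value,
            "n": n,
            "vte": int(vte),
            "vte_rate": (vte / n) if n else 0.0,
        })
    return rows


def _fit_to_dict(fit: LogisticFit) -> dict:
    return {
        "terms": [
            {"term": t, "beta": float(b), "se": float(s), "or": float(o),
             "ci_low": float(lo), "ci_high": float(hi), "p": float(p)}
            for t, b, s, o, lo, hi, p in zip(
                fit.terms, fit.beta, fit.se, fit.or_point,
                fit.ci_low, fit.ci_high, fit.p_values)
        ],
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "separation_detected": fit.separation_detected,
        "n_obs": fit.n_obs,
    }


def _roc_to_dict(roc: RocCurve) -> dict:
    cutoff, sens, spec = optimal_cutoff(roc)
    return {
        "thresholds": [None if np.isinf(t) else float(t) for t in roc.thresholds],
        "tpr": roc.tpr.tolist(),
        "fpr": roc.fpr.tolist(),
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "auc_ci": list(roc.auc_ci()),
        "cutoff": cutoff,
        "cutoff_sensitivity": sens,
        "cutoff_specificity": spec,
    }


def run_analysis(cohort: Cohort, options: Optional[AnalysisOptions] = None) -> AnalysisReport:
    """Run the full validation pipeline on a cohort with outcomes.

    Deterministic given the cohort; every sub-result equals the direct
    call of the corresponding stage operation.  Non-fatal stage problems
    (non-estimable screen rows, a multivariate step with no selectable
    factor, separation) are collected in ``flags``; a cohort without both
    outcome classes is a fatal degenerate input.
    """
    options = options or AnalysisOptions()
    cohort.validate().require_nonempty()
    n = len(cohort)
    vte_count = sum(r.vte for r in cohort)
    if vte_count == 0 or vte_count == n:
        raise ValueError("degenerate outcome: cohort must contain events and non-events")
    flags: list[str] = []
    log.info("analysis start: n=%d events=%d", n, vte_count)

    stratification = {ram.value: _stratify(cohort, ram) for ram in Ram}
    log.info("stratification done for %d models", len(stratification))

    diagnostics = {}
    for ram in Ram:
        table = build_two_by_two(
            cohort,
            exposure=lambda r, _ram=ram: score_patient(r, _ram).category is RiskCategory.HIGH,
            outcome=lambda r: r.vte,
        )
        metrics = diagnostic_metrics(table)
        roc_model = roc_curve([score_patient(r, ram).points for r in cohort],
                              [r.vte for r in cohort])
        diagnostics[ram.value] = {
            "tp": metrics.tp, "fn": metrics.fn, "fp": metrics.fp, "tn": metrics.tn,
            "values": {k: getattr(metrics, k)
                       for k in ("sensitivity", "specificity", "ppv", "npv")},
            "percent": metrics.as_percent(),
            "undefined": list(metrics.undefined),
            "c_statistic": roc_model.auc,
        }
    log.info("diagnostic metrics done")

    screen = univariate_screen(cohort, options.factors or default_factors())
    screen_table = screen.table.replace({np.nan: None}).to_dict(orient="records")
    for row in screen_table:
        if not row["estimable"]:
            flags.append(f"univariate screen: factor {row['factor']!r} flagged "
                         f"({row['note'] or 'non-estimable'})")
    log.info("univariate screen done: %d factors", len(screen_table))

    multivariate = None
    try:
        fit, selection_log = multivariate_model(cohort, screen, alpha_in=options.alpha_in)
        multivariate = _fit_to_dict(fit)
        multivariate["selection"] = selection_log
        if fit.separation_detected:
            flags.append("multivariate: separation detected; coefficients unreliable")
        for name, reason in selection_log["excluded"].items():
            if "separation" in reason or "non-estimable" in reason:
                flags.append(f"multivariate: factor {name!r} excluded — {reason}")
    except ValueError as exc:
        flags.append(f"multivariate: {exc}")
    log.info("multivariate stage done (fitted=%s)", multivariate is not None)

    compass_points = [score_patient(r, Ram.COMPASS_CAT).points for r in cohort]
    roc = _roc_to_dict(roc_curve(compass_points, [r.vte for r in cohort]))
    log.info("ROC stage done: auc=%.3f cutoff=%g", roc["auc"], roc["cutoff"])

    metadata = {
        "software": f"vteram {__version__}",
        "config_hash": options.config_hash(),
        "seed": options.seed,
        "provenance": cohort.provenance,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return AnalysisReport(
        n=n, vte_count=int(vte_count), vte_rate=vte_count / n,
        stratification=stratification, diagnostics=diagnostics,
        screen_table=screen_table, multivariate=multivariate,
        roc=roc, flags=flags, metadata=metadata,
    )
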