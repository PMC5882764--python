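"""Diagnostic-validation statistics for binary risk classifiers.

Implements the statistics used to validate a dichotomized risk score
against a binary outcome:

* 2x2 tabulation and the four diagnostic metrics (sensitivity,
  specificity, PPV, NPV) with exact binomial intervals,
* cross-product odds ratios with Woolf (logit) 95% intervals and the
  Haldane-Anscombe +0.5 correction for zero cells,
* Pearson chi-square (no continuity correction) and the Mann-Whitney U
  test (midranks; exact enumeration for small samples),
* ROC analysis: the empirical curve, trapezoidal AUC (the C statistic),
  the Hanley-McNeil standard error, and Youden-J optimal cutoff,
* binary logistic regression by maximum likelihood with Wald intervals,
  univariate factor screening and the screen-then-fit multivariate model.

Percentages in printed tables are rounded half-up (82.5 -> 83), matching
the convention of clinical diagnostic tables; all stored values keep full
precision.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import Cohort, PatientRecord

__all__ = [
    "TwoByTwo",
    "DiagnosticMetrics",
    "OddsRatioResult",
    "RocCurve",
    "LogisticFit",
    "ScreenResult",
    "build_two_by_two",
    "diagnostic_metrics",
    "odds_ratio_2x2",
    "chi_square_test",
    "mann_whitney_u",
    "roc_curve",
    "optimal_cutoff",
    "fit_logistic",
    "univariate_screen",
    "multivariate_model",
    "percent",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def percent(fraction: float, decimals: int = 0) -> float:
    """Round-half-up percentage: ``percent(0.825) == 83.0``.

    Clinical tables round half away from zero, not to even; 34.7 -> 35,
    82.5 -> 83, 15.4 -> 15.
    """
    scaled = fraction * 100.0 * 10 ** decimals
    return math.floor(scaled + 0.5) / 10 ** decimals


# --- 2x2 tables -------------------------------------------------------------

@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-outcome count table.

    ``a`` exposed & event, ``b`` unexposed & event, ``c`` exposed & no
    event, ``d`` unexposed & no event.  When the exposure is a positive
    risk-score test, ``a, b, c, d`` read as ``tp, fn, fp, tn``.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0 or value != int(value):
                raise ValueError(f"cell {name} must be a non-negative integer, got {value}")
        if self.total < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def events(self) -> int:
        return self.a + self.b

    @property
    def exposed(self) -> int:
        return self.a + self.c

    def as_array(self) -> np.ndarray:
        """Rows = exposure (yes/no), columns = outcome (event/no event)."""
        return np.array([[self.a, self.c], [self.b, self.d]], dtype=float)


def build_two_by_two(
    cohort: Cohort,
    exposure: Callable[[PatientRecord], bool],
    outcome: Callable[[PatientRecord], bool],
) -> TwoByTwo:
    """Tabulate a cohort by an exposure predicate against an outcome predicate."""
    cohort.require_nonempty()
    a = b = c = d = 0
    for record in cohort:
        e, o = bool(exposure(record)), bool(outcome(record))
        if e and o:
            a += 1
        elif not e and o:
            b += 1
        elif e:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


# --- diagnostic metrics -----------------------------------------------------

@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV of a dichotomous test.

    Each proportion carries an exact (Clopper-Pearson) binomial 95%
    interval.  A metric with a zero denominator is ``None`` — flagged in
    ``undefined`` rather than silently reported as 0.
    """

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    intervals: dict = field(default_factory=dict)
    undefined: tuple[str, ...] = ()

    def as_percent(self, decimals: int = 0) -> dict[str, Optional[float]]:
        """The four metrics as rounded percentages (half-up)."""
        return {
            name: (None if value is None else percent(value, decimals))
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def _ratio_with_ci(num: int, den: int):
    if den == 0:
        return None, None
    # Clopper-Pearson exact interval
    low = 0.0 if num == 0 else sps.beta.ppf(0.025, num, den - num + 1)
    high = 1.0 if num == den else sps.beta.ppf(0.975, num + 1, den - num)
    return num / den, (float(low), float(high))


def diagnostic_metrics(table: TwoByTwo) -> DiagnosticMetrics:
    """Diagnostic metrics of a 2x2 table read as test-positive = exposed.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    ppv = tp/(tp+fp), npv = tn/(tn+fn).
    """
    tp, fn, fp, tn = table.a, table.b, table.c, table.d
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("diagnostic metrics need at least one event and one non-event")
    values, intervals, undefined = {}, {}, []
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        value, ci = _ratio_with_ci(num, den)
        values[name] = value
        if value is None:
            undefined.append(name)
        else:
            intervals[name] = ci
    return DiagnosticMetrics(tp=tp, fn=fn, fp=fp, tn=tn,
                             intervals=intervals, undefined=tuple(undefined), **values)


# --- odds ratio -------------------------------------------------------------

@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product odds ratio with a Woolf (logit) 95% interval."""

    or_point: float
    ci_low: float
    ci_high: float
    log_or_se: float
    correction_applied: bool
    estimable: bool = True


def odds_ratio_2x2(table: TwoByTwo) -> OddsRatioResult:
    """Cross-product OR = ad/bc with SE(ln OR) = sqrt(1/a+1/b+1/c+1/d).

    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells first and ``correction_applied`` is set.  A table with two
    zero cells on a diagonal has no finite, informative OR even after
    correction; the result is flagged ``estimable=False``.
    """
    if table.total < 4:
        raise ValueError("odds ratio needs at least 4 observations")
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    correction = any(x == 0 for x in (a, b, c, d))
    # a double-zero diagonal, a constant exposure or a constant outcome
    # leaves no information about the odds ratio even after correction
    estimable = not (
        (a == 0 and d == 0) or (b == 0 and c == 0)
        or a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0
    )
    if correction:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_point)
    return OddsRatioResult(
        or_point=or_point,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        log_or_se=se,
        correction_applied=correction,
        estimable=estimable,
    )


# --- hypothesis tests -------------------------------------------------------

def chi_square_test(table: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin: chi-square requires positive row/column totals")
    statistic, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


def _mwu_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U uses midranks for ties.  For small samples (both n <= 8) the p-value
    is exact, by enumeration of all assignments of the pooled values to
    the two groups; otherwise the normal approximation with tie correction
    is used.  If every pooled value is identical the test is degenerate
    and p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _mwu_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0
    mu = n1 * n2 / 2.0
    if n1 <= 8 and n2 <= 8:
        # exact two-sided p: share of group assignments at least as extreme
        deviations = []
        indices = range(n1 + n2)
        for combo in itertools.combinations(indices, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            deviations.append(abs(_mwu_statistic(pooled[mask], pooled[~mask]) - mu))
        deviations = np.asarray(deviations)
        p = float(np.mean(deviations >= abs(u - mu) - 1e-12))
        return u, p
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u - mu) / math.sqrt(sigma2)
    return u, float(2 * sps.norm.sf(abs(z)))


# --- ROC --------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve of a score against a binary label.

    A score is test-positive at threshold ``t`` when score >= t.
    ``thresholds`` is descending and starts with +inf (the empty-positive
    corner (0, 0)); the final threshold is the minimum score, where the
    curve reaches (1, 1).  ``auc`` is the trapezoidal area, identical to
    the Mann-Whitney concordance probability with ties counted 1/2 — the
    C statistic.  ``auc_se`` is the Hanley-McNeil standard error.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_se: float
    n_events: int
    n_nonevents: int

    def auc_ci(self) -> tuple[float, float]:
        """Normal-approximation 95% interval for the AUC, clipped to [0, 1]."""
        return (max(0.0, self.auc - Z95 * self.auc_se),
                min(1.0, self.auc + Z95 * self.auc_se))


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC curve; one threshold per distinct score, descending."""
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int(labels.sum())
    n0 = int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC analysis requires both classes present")
    distinct = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], distinct])
    tpr = np.empty_like(thresholds)
    fpr = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        positive = scores >= t
        tpr[i] = (positive & labels).sum() / n1
        fpr[i] = (positive & ~labels).sum() / n0
    auc = float(np.trapezoid(tpr, fpr))
    # Hanley-McNeil SE
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2) + (n0 - 1) * (q2 - auc ** 2)) / (n1 * n0)
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr,
                    auc=auc, auc_se=math.sqrt(max(var, 0.0)),
                    n_events=n1, n_nonevents=n0)


def optimal_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden J = sensitivity + specificity - 1.

    Only real score thresholds are candidates (not the +inf sentinel);
    ties break toward the higher threshold, i.e. fewer test-positives.
    """
    best = None
    for t, se, sp in zip(roc.thresholds[1:], roc.tpr[1:], 1.0 - roc.fpr[1:]):
        j = se + sp - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), float(se), float(sp))
    assert best is not None
    _, cutoff, sensitivity, specificity = best
    return cutoff, sensitivity, specificity


# --- logistic regression ----------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Binary logistic regression fit with Wald inference.

    ``or_point[k] = exp(beta[k])`` and the 95% bounds are
    ``exp(beta ± 1.96 se)`` for every non-intercept term.  When the data
    are (quasi-)separated the MLE diverges; the fit is returned with
    ``separation_detected`` set and its coefficients must not be trusted.
    """

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    or_point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    converged: bool
    separation_detected: bool
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_values,
        })


class SeparationWarning(UserWarning):
    """The logistic MLE is diverging because a predictor separates the outcome."""


def fit_logistic(design: pd.DataFrame, outcome: Sequence[bool]) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome.

    ``design`` holds one column per predictor (binary or real); an
    intercept is always added.  Newton iterations are tried first (score
    tolerance 1e-8, up to 100 iterations); if the information matrix
    degenerates — the signature of separation — a quasi-Newton fallback is
    used and the fit inspected: any fitted probability within 1e-6 of 0 or
    1 together with a diverging coefficient sets ``separation_detected``.
    """
    y = np.asarray(list(outcome), dtype=float)
    if design.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    if design.shape[1] == 0:
        X = np.ones((len(y), 1))  # intercept-only model
    else:
        X = sm.add_constant(np.asarray(design, dtype=float), has_constant="add")
    terms = ("intercept", *map(str, design.columns))
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            result = model.fit(disp=0, method="bfgs", maxiter=500)
    beta = np.asarray(result.params, dtype=float)
    try:
        se = np.asarray(result.bse, dtype=float)
    except np.linalg.LinAlgError:
        se = np.full_like(beta, np.nan)
    phat = result.predict(X)
    boundary = bool(np.any((phat < 1e-6) | (phat > 1 - 1e-6)))
    separation = boundary and bool(np.any(np.abs(beta) > 10.0))
    converged = bool(result.mle_retvals.get("converged", False)) and not separation
    if not converged and not separation:
        raise RuntimeError(
            f"logistic fit failed to converge without separation: {result.mle_retvals}"
        )
    if separation:
        warnings.warn(
            "perfect/quasi-complete separation detected; coefficients are not trustworthy",
            SeparationWarning,
            stacklevel=2,
        )
    with np.errstate(over="ignore"):
        or_point = np.exp(beta)
        ci_low = np.exp(beta - Z95 * se)
        ci_high = np.exp(beta + Z95 * se)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    p_values = 2 * sps.norm.sf(np.abs(z))
    return LogisticFit(
        terms=terms, beta=beta, se=se, or_point=or_point,
        ci_low=ci_low, ci_high=ci_high, p_values=p_values,
        log_likelihood=float(result.llf), converged=converged or separation,
        separation_detected=separation, n_obs=len(y),
    )


# --- univariate screen and multivariate model -------------------------------

@dataclass
class ScreenResult:
    """Univariate factor screen: one OR + chi-square row per factor.

    Keeps the factor predicates so the multivariate step can rebuild the
    design matrix for the factors that survive selection.
    """

    table: pd.DataFrame
    factors: dict[str, Callable[[PatientRecord], bool]]
    outcome: Callable[[PatientRecord], bool]


def univariate_screen(
    cohort: Cohort,
    factors: Sequence[tuple[str, Callable[[PatientRecord], bool]]],
    outcome: Callable[[PatientRecord], bool] = lambda r: r.vte,
) -> ScreenResult:
    """Screen each candidate factor against the outcome, one 2x2 at a time.

    Each row carries the cross-product OR with Woolf interval and the
    Pearson chi-square p-value.  A factor whose table is degenerate
    (constant factor, zero margin) is flagged, never fatal.
    """
    cohort.require_nonempty()
    if not factors:
        raise ValueError("at least one factor is required")
    rows = []
    for name, predicate in factors:
        table = build_two_by_two(cohort, predicate, outcome)
        row = {"factor": name, "a": table.a, "b": table.b, "c": table.c, "d": table.d,
               "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
               "estimable": False, "correction_applied": False, "note": ""}
        try:
            orr = odds_ratio_2x2(table)
            row.update({"or": orr.or_point, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
                        "estimable": orr.estimable,
                        "correction_applied": orr.correction_applied})
            if not orr.estimable:
                row["note"] = "non-estimable odds ratio (degenerate table)"
        except ValueError as exc:
            row["note"] = f"odds ratio: {exc}"
        try:
            _, p = chi_square_test(table)
            row["p"] = p
        except ValueError as exc:
            row["note"] = (row["note"] + "; " if row["note"] else "") + f"chi-square: {exc}"
        rows.append(row)
    return ScreenResult(table=pd.DataFrame(rows), factors=dict(factors), outcome=outcome)


def _separates(table: TwoByTwo) -> bool:
    """A zero cell in the factor-by-outcome table induces quasi-complete
    separation of the logistic MLE."""
    return 0 in (table.a, table.b, table.c, table.d)


def multivariate_model(
    cohort: Cohort,
    screen: ScreenResult,
    alpha_in: float = 0.01,
) -> tuple[LogisticFit, dict]:
    """Fit the multivariate logistic model on screen-selected factors.

    Factors enter when their univariate chi-square p < ``alpha_in``;
    non-estimable factors and factors that would separate the outcome
    (a zero cell against the outcome) are excluded and logged.  Returns
    the fit and a log of the selection decisions.
    """
    log = {"selected": [], "excluded": {}}
    for _, row in screen.table.iterrows():
        name = row["factor"]
        if not np.isfinite(row["p"]) or row["p"] >= alpha_in:
            log["excluded"][name] = f"univariate p {row['p']:.4g} >= {alpha_in}"
            continue
        if not row["estimable"]:
            log["excluded"][name] = "non-estimable univariate odds ratio"
            continue
        table = TwoByTwo(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
        if _separates(table):
            log["excluded"][name] = "would induce separation (zero cell against outcome)"
            continue
        log["selected"].append(name)
    if not log["selected"]:
        raise ValueError(
            f"no factor passed the univariate screen at alpha_in={alpha_in}; "
            "consider a larger alpha_in"
        )
    design = pd.DataFrame({
        name: [float(screen.factors[name](r)) for r in cohort]
        for name in log["selected"]
    })
    outcome = [screen.outcome(r) for r in cohort]
    return fit_logistic(design, outcome), log
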