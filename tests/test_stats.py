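"""Validation statistics: 2x2 metrics, odds ratios, tests, ROC, logistic fit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vteram import (
    TwoByTwo,
    build_two_by_two,
    chi_square_test,
    diagnostic_metrics,
    fit_logistic,
    mann_whitney_u,
    multivariate_model,
    odds_ratio_2x2,
    optimal_cutoff,
    percent,
    roc_curve,
    univariate_screen,
)

cells = st.integers(min_value=0, max_value=200)


class TestTwoByTwo:
    def test_build_partitions_cohort(self, synthetic_cohort_118):
        cohort = synthetic_cohort_118
        table = build_two_by_two(cohort, lambda r: r.atrial_fibrillation,
                                 lambda r: r.vte)
        assert table.total == len(cohort)
        # independent marginal oracle
        assert table.events == sum(r.vte for r in cohort)
        assert table.exposed == sum(r.atrial_fibrillation for r in cohort)

    def test_exposure_equal_outcome_gives_empty_off_diagonal(self, small_cohort):
        table = build_two_by_two(small_cohort, lambda r: r.vte, lambda r: r.vte)
        assert table.b == table.c == 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 5)


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("table,expected", [
        # (tp, fn, fp, tn) -> rounded percent metrics
        (TwoByTwo(20, 0, 64, 34),
         {"sensitivity": 100, "specificity": 35, "ppv": 24, "npv": 100}),
        (TwoByTwo(2, 18, 13, 85),
         {"sensitivity": 10, "specificity": 87, "ppv": 13, "npv": 83}),
        (TwoByTwo(5, 0, 0, 5),
         {"sensitivity": 100, "specificity": 100, "ppv": 100, "npv": 100}),
    ])
    def test_worked_tables(self, table, expected):
        assert diagnostic_metrics(table).as_percent() == expected

    def test_zero_denominator_is_flagged_not_zero(self):
        metrics = diagnostic_metrics(TwoByTwo(0, 5, 0, 5))  # nobody test-positive
        assert metrics.ppv is None
        assert "ppv" in metrics.undefined

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=200, deadline=None)
    def test_ratio_identities(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        m = diagnostic_metrics(TwoByTwo(a, b, c, d))
        if m.sensitivity is not None:
            assert m.sensitivity * (m.tp + m.fn) == pytest.approx(m.tp)
        if m.specificity is not None:
            assert m.specificity * (m.tn + m.fp) == pytest.approx(m.tn)
        if m.ppv is not None:
            assert m.ppv * (m.tp + m.fp) == pytest.approx(m.tp)
        if m.npv is not None:
            assert m.npv * (m.tn + m.fn) == pytest.approx(m.tn)

    @pytest.mark.parametrize("fraction,decimals,expected", [
        (0.347, 0, 35.0), (0.825, 0, 83.0), (0.154, 0, 15.0),
        (0.133, 0, 13.0), (20 / 118, 1, 16.9), (0.238, 1, 23.8),
    ])
    def test_percent_rounds_half_up(self, fraction, decimals, expected):
        assert percent(fraction, decimals) == expected


class TestOddsRatio:
    def test_atrial_fibrillation_table(self):
        r = odds_ratio_2x2(TwoByTwo(7, 13, 6, 92))
        assert r.or_point == pytest.approx(8.26, abs=0.005)
        assert r.ci_low == pytest.approx(2.40, abs=0.005)
        # the published upper bound 28.41 carries intermediate rounding;
        # the exact Woolf bound is 28.404
        assert r.ci_high == pytest.approx(28.41, abs=0.015)
        assert not r.correction_applied

    def test_chronic_kidney_disease_table(self):
        r = odds_ratio_2x2(TwoByTwo(6, 14, 9, 89))
        assert r.or_point == pytest.approx(4.24, abs=0.005)
        assert r.ci_low == pytest.approx(1.31, abs=0.005)
        assert r.ci_high == pytest.approx(13.75, abs=0.005)

    def test_symmetric_table_is_unity(self):
        assert odds_ratio_2x2(TwoByTwo(1, 1, 1, 1)).or_point == pytest.approx(1.0)

    def test_zero_cell_haldane_anscombe(self):
        r = odds_ratio_2x2(TwoByTwo(20, 0, 46, 52))
        assert r.correction_applied
        assert r.or_point == pytest.approx((20.5 * 52.5) / (0.5 * 46.5))

    def test_double_zero_diagonal_flagged(self):
        r = odds_ratio_2x2(TwoByTwo(0, 5, 5, 0))
        assert not r.estimable

    @given(a=st.integers(1, 100), b=st.integers(1, 100),
           c=st.integers(1, 100), d=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_invariances(self, a, b, c, d):
        base = odds_ratio_2x2(TwoByTwo(a, b, c, d))
        # simultaneous row+column swap leaves the OR unchanged
        swapped = odds_ratio_2x2(TwoByTwo(d, c, b, a))
        assert swapped.or_point == pytest.approx(base.or_point)
        # relabeling the exposure maps the OR to its reciprocal
        relabeled = odds_ratio_2x2(TwoByTwo(b, a, d, c))
        assert relabeled.or_point == pytest.approx(1.0 / base.or_point)
        assert base.ci_low <= base.or_point <= base.ci_high


class TestChiSquare:
    @pytest.mark.parametrize("table,p_printed", [
        (TwoByTwo(7, 13, 6, 92), 0.0002),     # AF vs VTE
        (TwoByTwo(25, 5, 51, 37), 0.0122),    # high comorbidity score vs death
    ])
    def test_published_p_values(self, table, p_printed):
        _, p = chi_square_test(table)
        assert round(p, 4) == p_printed

    def test_equal_proportions(self):
        statistic, p = chi_square_test(TwoByTwo(10, 10, 10, 10))
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test(TwoByTwo(5, 5, 0, 0))


class TestMannWhitney:
    def test_maximal_separation(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_all_values_identical_degenerate(self):
        _, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_exact_p_matches_permutation_oracle(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0]
        u_obs, p = mann_whitney_u(x, y)
        pooled = sorted(x + y)
        mu = len(x) * len(y) / 2

        def u_of(idx):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(5) if i not in idx]
            return sum(sum(xv > yv for yv in ys) + 0.5 * sum(xv == yv for yv in ys)
                       for xv in xs)

        deviations = [abs(u_of(c) - mu) for c in itertools.combinations(range(5), 3)]
        expected = sum(dev >= abs(u_obs - mu) - 1e-12 for dev in deviations) / len(deviations)
        assert p == pytest.approx(expected)

    def test_large_sample_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        from scipy.stats import mannwhitneyu
        u, p = mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        roc = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        cutoff, sens, spec = optimal_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert cutoff == 10

    def test_uninformative_ties_auc_half(self):
        roc = roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.5)
        _, sens, spec = optimal_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_auc_equals_pairwise_concordance(self):
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 1, 0, 1, 1]
        roc = roc_curve(scores, labels)
        pairs = [(s1, s0) for s1, l1 in zip(scores, labels) if l1
                 for s0, l0 in zip(scores, labels) if not l0]
        concordance = sum((s1 > s0) + 0.5 * (s1 == s0) for s1, s0 in pairs) / len(pairs)
        assert roc.auc == pytest.approx(concordance)

    def test_endpoints_and_monotonicity(self, synthetic_cohort_118):
        from vteram import Ram
        from vteram.scores import score_patient
        points = [score_patient(r, Ram.COMPASS_CAT).points for r in synthetic_cohort_118]
        labels = [r.vte for r in synthetic_cohort_118]
        roc = roc_curve(points, labels)
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    @given(st.lists(st.tuples(st.integers(0, 10), st.booleans()),
                    min_size=4, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_auc_concordance_and_label_flip(self, data):
        scores = [float(s) for s, _ in data]
        labels = [l for _, l in data]
        if len(set(labels)) < 2:
            return
        roc = roc_curve(scores, labels)
        pairs = [(s1, s0) for s1, l1 in zip(scores, labels) if l1
                 for s0, l0 in zip(scores, labels) if not l0]
        concordance = sum((s1 > s0) + 0.5 * (s1 == s0) for s1, s0 in pairs) / len(pairs)
        assert roc.auc == pytest.approx(concordance)
        flipped = roc_curve(scores, [not l for l in labels])
        assert flipped.auc == pytest.approx(1.0 - roc.auc)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 15, 200).astype(float)
        labels = rng.random(200) < 0.3
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [1, 1, 1])

    def test_cutoff_matches_exhaustive_search(self):
        scores = [1, 2, 2, 3, 4, 5, 6, 7]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        roc = roc_curve(scores, labels)
        cutoff, sens, spec = optimal_cutoff(roc)
        n1, n0 = sum(labels), len(labels) - sum(labels)
        best_j, best_t = -2.0, None
        for t in sorted(set(scores), reverse=True):
            se = sum(l and s >= t for s, l in zip(scores, labels)) / n1
            sp = sum((not l) and s < t for s, l in zip(scores, labels)) / n0
            # ties break toward the higher threshold, examined first
            if se + sp - 1 > best_j + 1e-12:
                best_j, best_t = se + sp - 1, t
        assert cutoff == best_t
        assert sens + spec - 1 == pytest.approx(best_j)


class TestLogistic:
    def test_single_binary_predictor_reproduces_2x2_or(self):
        # AF table: 13 exposed (7 events), 105 unexposed (13 events)
        x = [1.0] * 13 + [0.0] * 105
        y = [True] * 7 + [False] * 6 + [True] * 13 + [False] * 92
        fit = fit_logistic(pd.DataFrame({"af": x}), y)
        closed = odds_ratio_2x2(TwoByTwo(7, 13, 6, 92))
        assert fit.or_point[1] == pytest.approx(closed.or_point, rel=1e-6)
        assert fit.se[1] == pytest.approx(closed.log_or_se, rel=1e-6)
        assert fit.ci_low[1] == pytest.approx(closed.ci_low, rel=1e-4)
        assert fit.ci_high[1] == pytest.approx(closed.ci_high, rel=1e-4)

    @pytest.mark.parametrize("a,b,c,d", [(5, 9, 11, 20), (30, 12, 7, 44), (3, 8, 5, 13)])
    def test_mle_equals_cross_product_on_2x2(self, a, b, c, d):
        x = [1.0] * (a + c) + [0.0] * (b + d)
        y = [True] * a + [False] * c + [True] * b + [False] * d
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        closed = odds_ratio_2x2(TwoByTwo(a, b, c, d))
        assert fit.or_point[1] == pytest.approx(closed.or_point, rel=1e-6)
        assert fit.se[1] == pytest.approx(closed.log_or_se, rel=1e-6)

    def test_intercept_only_recovers_event_fraction(self):
        y = [True] * 7 + [False] * 33
        fit = fit_logistic(pd.DataFrame(index=range(40)), y)
        p = 1 / (1 + math.exp(-fit.beta[0]))
        assert p == pytest.approx(7 / 40, rel=1e-6)

    def test_separation_detected_and_flagged(self):
        # exposure present in all events: quasi-complete separation
        x = [1.0] * 20 + [1.0] * 46 + [0.0] * 52
        y = [True] * 20 + [False] * 98
        with pytest.warns(UserWarning):
            fit = fit_logistic(pd.DataFrame({"hosp": x}), y)
        assert fit.separation_detected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), [True, True])


class TestScreenAndMultivariate:
    def test_screen_agrees_with_manual_calls(self, synthetic_cohort_118):
        cohort = synthetic_cohort_118
        factors = [("af", lambda r: r.atrial_fibrillation),
                   ("gem", lambda r: r.gemcitabine_chemo)]
        screen = univariate_screen(cohort, factors)
        for _, row in screen.table.iterrows():
            predicate = dict(factors)[row["factor"]]
            table = build_two_by_two(cohort, predicate, lambda r: r.vte)
            if row["estimable"]:
                assert row["or"] == pytest.approx(odds_ratio_2x2(table).or_point)
            assert row["p"] == pytest.approx(chi_square_test(table)[1])

    def test_constant_factor_flagged_not_fatal(self, synthetic_cohort_118):
        screen = univariate_screen(synthetic_cohort_118,
                                   [("never", lambda r: False)])
        row = screen.table.iloc[0]
        assert not row["estimable"]
        assert row["note"]

    def test_alpha_one_admits_all_estimable_factors(self, synthetic_cohort_2000):
        cohort = synthetic_cohort_2000
        factors = [("af", lambda r: r.atrial_fibrillation),
                   ("gem", lambda r: r.gemcitabine_chemo),
                   ("ckd", lambda r: r.chronic_kidney_disease)]
        screen = univariate_screen(cohort, factors)
        fit, log = multivariate_model(cohort, screen, alpha_in=1.0)
        assert set(log["selected"]) == {"af", "gem", "ckd"}
        assert fit.converged

    def test_separating_factor_excluded(self, make_patient):
        from vteram import Cohort
        # hospitalization present in 100% of events
        records = []
        for i in range(20):
            records.append(make_patient(patient_id=f"E{i}", vte=True,
                                        vte_time_months=1.0,
                                        recent_hospitalization=True,
                                        atrial_fibrillation=i < 10))
        for i in range(98):
            records.append(make_patient(patient_id=f"N{i}",
                                        recent_hospitalization=i < 46,
                                        atrial_fibrillation=i < 6))
        cohort = Cohort(records=records).validate()
        screen = univariate_screen(cohort, [
            ("hosp", lambda r: r.recent_hospitalization),
            ("af", lambda r: r.atrial_fibrillation),
        ])
        fit, log = multivariate_model(cohort, screen, alpha_in=0.01)
        assert "hosp" in log["excluded"]
        assert "separation" in log["excluded"]["hosp"]
        assert log["selected"] == ["af"]
        assert not fit.separation_detected

    def test_no_survivor_raises_with_advice(self, synthetic_cohort_118):
        screen = univariate_screen(synthetic_cohort_118,
                                   [("sex", lambda r: r.sex == "male")])
        with pytest.raises(ValueError, match="alpha_in"):
            multivariate_model(synthetic_cohort_118, screen, alpha_in=1e-12)
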