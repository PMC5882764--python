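"""Generate a synthetic 118-patient cohort and run the full validation.

The generator draws covariates from the reference population's marginal
prevalences and the VTE outcome from a logistic model (high COMPASS-CAT
OR 8.73, gemcitabine OR 3.37, atrial fibrillation OR 7.19, overall rate
calibrated to 16.9%).  The report prints the study-shaped tables: risk
stratification per model, diagnostic metrics, the univariate screen, the
multivariate fit and the COMPASS-CAT ROC analysis.
"""

from vteram import SyntheticConfig, generate_cohort, run_analysis

cohort = generate_cohort(SyntheticConfig(n=118, seed=42))
report = run_analysis(cohort)
print(report.to_text())
print("Sampling noise at n=118 is large: single-cohort odds ratios and the")
print("AUC wander around the generating values; rerun with n=10000 to see")
print("them settle near OR 8.73 / 3.37 / 7.19.")
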