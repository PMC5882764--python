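"""Recompute a published validation study's metrics from its printed counts.

The 2x2 count tables of the reference 118-patient lung-cancer study are
public numbers; feeding them through the package's diagnostic-metric,
odds-ratio and chi-square operations reproduces the printed results.
"""

from vteram import TwoByTwo, chi_square_test, diagnostic_metrics, odds_ratio_2x2

print("COMPASS-CAT high-risk split, (tp, fn, fp, tn) = (20, 0, 64, 34):")
metrics = diagnostic_metrics(TwoByTwo(20, 0, 64, 34))
for name, value in metrics.as_percent().items():
    print(f"  {name:<12} {value:.0f}%")
print("  -> the high-risk group captured every VTE event (sensitivity 100%,")
print("     NPV 100%) at the cost of 64 false positives (specificity 35%).")

print()
print("Atrial fibrillation vs VTE, (a, b, c, d) = (7, 13, 6, 92):")
af = odds_ratio_2x2(TwoByTwo(7, 13, 6, 92))
_, p = chi_square_test(TwoByTwo(7, 13, 6, 92))
print(f"  OR {af.or_point:.2f} (95% CI {af.ci_low:.2f}-{af.ci_high:.2f}), "
      f"chi-square p = {p:.4f}")
print("  -> patients with atrial fibrillation had ~8-fold higher odds of VTE;")
print("     the Woolf interval excludes 1, and the association is significant.")

print()
print("Chronic kidney disease vs VTE, (6, 14, 9, 89):")
ckd = odds_ratio_2x2(TwoByTwo(6, 14, 9, 89))
print(f"  OR {ckd.or_point:.2f} (95% CI {ckd.ci_low:.2f}-{ckd.ci_high:.2f})")
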