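"""Estimate the precision of a score-guided MPRA screen via Bayes' rule.

Given a validation-set recall at a chosen top-fraction threshold, an assumed
genome-wide prevalence of MPRA-functional variants, and the fraction of the
candidate pool the budget covers, the expected precision of the screen is

    P(+ | predict+) = recall * prevalence / fraction_predicted

The two source assays ran unscreened candidate pools at precisions
0.030 (678/22,803) and 0.057 (1684/29,685); a well-calibrated screen should
beat both at comparable budgets.
"""

import mpradesign as m

print(f"assay baselines: {678/22_803:.3f} (678/22,803) and {1684/29_685:.3f} (1684/29,685)\n")

pool = 9_200_000
# recall grows with budget, as a threshold-sweep on a validation set would show
recall_at_budget = {25_000: 0.10, 50_000: 0.15, 75_000: 0.20, 100_000: 0.25}
print("budget  fraction  recall  precision at prevalence 0.005 / 0.01 / 0.02")
for n_tested, recall in recall_at_budget.items():
    frac = m.fraction_for_count(n_tested, pool)
    cells = [m.bayes_precision(recall, prev, frac).precision for prev in (0.005, 0.01, 0.02)]
    print(f"{n_tested:>7} {frac:>8.3f} {recall:>7.2f}  " + "  /  ".join(f"{p:.3f}" for p in cells))
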