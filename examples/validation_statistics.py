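"""Quality statistics for loss predictions against experimental labels.

Starting from published genome-wide validation tallies (loss events correctly
predicted vs missed; retention events wrongly vs correctly predicted), this
computes the true/false positive rates and asks, with a two-sided Fisher's
exact test, whether the predictor beats a random one (for which TPR = FPR).
"""

import isoppi as ip

tallies = {
    "full DDI annotations only (34 reference interactions)":
        ip.ConfusionCounts(tp=9, fn=18, fp=3, tn=12),
    "full + partial annotations (260 reference interactions)":
        ip.ConfusionCounts(tp=53, fn=118, fp=12, tn=105),
}

for label, counts in tallies.items():
    res = ip.fisher_exact_two_sided(counts.as_table())
    print(f"\n{label}")
    print(f"  TPR = {counts.tp}/{counts.tp + counts.fn} = {counts.tpr:.2f}   "
          f"FPR = {counts.fp}/{counts.fp + counts.tn} = {counts.fpr:.2f}")
    print(f"  two-sided Fisher's exact: p = {res.p:.2g} "
          f"(odds ratio {res.odds_ratio:.2f})")

print("\nA TPR above the FPR means predictions beat random guessing; the "
      "Fisher p-value\nsays whether the separation is significant at the "
      "given sample size.")
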