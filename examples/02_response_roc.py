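"""Predicting somatostatin-analogue response from SSTR2 immunoreactivity.

Runs the ROC analysis of the embedded 14-case SSA-treated GI-NET cohort:
each case carries three SSTR2 scores (digital composite, Volante, IRS) and
a dichotomized RECIST response (CR/SD = responder, PD = non-responder).

Run:  python examples/02_response_roc.py
"""

from sstr2dia import reproduce_response_roc

report = reproduce_response_roc()
print(f"{report['n_cases']} SSA-treated cases\n")
for name, s in report["scores"].items():
    print(f"{name:8s} AUC={s['auc']:.4f}  cutoff={s['cutoff']:g}  "
          f"sens={s['sensitivity']:.0%}  spec={s['specificity']:.0%}")
print("\nThe digital composite (dia) gives the highest AUC and, unlike the "
      "eyeball scores,\nbalances sensitivity with specificity at its Youden "
      "cutoff.\n")
for pair, t in report["delong"].items():
    print(f"DeLong {pair:18s} z={t['z']:+.3f}  p_adj={t['p_adjusted']:.3f}")
print("\nNo pairwise AUC difference is significant after Bonferroni "
      "correction —\nthe cohort is small, so the methods are statistically "
      "indistinguishable here.")
print(f"\n{report['volante_positive_response_rate']:.0f}% of Volante-positive "
      "(score >= 2) cases responded to treatment.")
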