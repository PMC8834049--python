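"""Generate a synthetic GI-NET cohort with site-dependent correlation
structure and verify its statistical shape.

Foregut-like tumors get a negative SSTR2-score/Ki-67 rank correlation and
hindgut-like tumors a positive one, mimicking the opposing trends seen in
resected series.

Run:  python examples/05_synthetic_cohort.py
"""

from sstr2dia import stats, synthetic

spec = synthetic.CohortSpec(
    n_per_site={"foregut": 60, "hindgut": 60},
    score_ki67_correlation={"foregut": -0.37, "hindgut": 0.33},
    response_model=synthetic.ResponseModel(intercept=0.4, slope=1.5),
)
table, meta = synthetic.generate_cohort(spec, seed=1)

for site, target in spec.score_ki67_correlation.items():
    sub = table[table.site_class == site]
    rho, p = stats.spearman(sub.dia_score, sub.ki67_li)
    print(f"{site:8s} n={len(sub)}  target rho={target:+.2f}  "
          f"realized rho={rho:+.3f} (p={p:.3g})")

auc = stats.auc_mann_whitney(table.dia_score, table.response_binary)
print(f"\nDIA score vs simulated response: AUC={auc:.3f}")
print("grades:", table.grade.value_counts().to_dict())
print("\nRealized rank correlations sit on their targets; the logistic "
      "response model\nmakes the DIA score an informative (AUC > 0.5) "
      "response predictor.")
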