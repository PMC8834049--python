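"""SSTR2 expression of normal neuroendocrine cells along the gut.

Compares the SSTR2/chromogranin-A double-stain positive rates of the
embedded 37-specimen normal-mucosa cohort between sites (Wilcoxon rank-sum,
Bonferroni-corrected over the two planned contrasts).

Run:  python examples/03_mucosa_rates.py
"""

from sstr2dia import reproduce_mucosa_rates

report = reproduce_mucosa_rates()
for site, med in report["medians"].items():
    print(f"{site:9s} n={report['n_per_site'][site]:2d}  median rate={med:.3f}")
for contrast in ("stomach_vs_rectum", "duodenum_vs_rectum"):
    c = report[contrast]
    print(f"{contrast}: p={c['p']:.2e} (adjusted {c['p_adjusted']:.2e})")
print("\nRectal neuroendocrine cells express far less SSTR2 than gastric or "
      "duodenal ones —\nconsistent with hindgut NETs inheriting low SSTR2 "
      "from their normal counterparts.")
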