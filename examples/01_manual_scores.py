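"""Manual SSTR2/Ki-67 scoring: Volante score, IRS, Ki-67 LI and WHO grade.

Run:  python examples/01_manual_scores.py
"""

from sstr2dia import scoring

# A tumor with strong circumferential membrane staining in 85% of cells
v = scoring.volante_score("membranous", "circumferential", 85)
i = scoring.irs(85, intensity=3)
print(f"Volante score: {v} (3 = circumferential membranous staining in >50% of cells)")
print(f"IRS:           {i} (positivity bin 4 for >80% x intensity 3 = 12, the maximum)")

# Ki-67 counting: 17 positive of 1000 tumor nuclei, truncated to 2 decimals
li = scoring.ki67_li(17, 1000)
print(f"Ki-67 LI:      {li}% -> WHO grade {scoring.who_grade(li)} "
      "(G1 < 3%, G2 3-20%, G3 > 20%)")

# Normal mucosa: 1 SSTR2/chromogranin-A double-positive cell of 23
# chromogranin-positive neuroendocrine cells, truncated to 4 decimals
rate = scoring.double_stain_rate(1, 23)
print(f"Double-stain positive rate: {rate} "
      "(fraction of neuroendocrine cells expressing SSTR2)")
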