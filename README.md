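# sstr2dia

Quantification of membranous **SSTR2 immunostaining** in gastrointestinal
neuroendocrine tumors (GI-NETs), and the statistics that link it to
somatostatin-analogue (SSA) treatment response and anatomical site.

SSTR2 (somatostatin receptor 2) is a membrane receptor whose expression on
tumor cells predicts benefit from SSAs such as octreotide and lanreotide.
Pathologists score its immunohistochemical (IHC) staining either by eye —
the **Volante score** (0–3, combining localization, circumferential vs
incomplete membrane staining, and fraction of positive cells) and the
**immunoreactive score** (IRS, positivity bin 0–4 × intensity 0–3, range
0–12) — or by digital image analysis (DIA), which measures every cell. This
package implements all three, plus the machinery to compare them as
response predictors. It is aimed at pathology-informatics researchers who
want a transparent, fully tested reimplementation of the DIA membrane
contract and the accompanying statistics.

## What is inside

- **`sstr2dia.membrane`** — the DIA pipeline: Ruifrok–Johnston color
  deconvolution with the DAB optical-density vector (0.268, 0.570, 0.776),
  nucleus segmentation with watershed splitting and territory expansion,
  per-cell membrane ring measurement (mean DAB OD and *membrane
  completeness* — the fraction of 10° sectors with supra-threshold signal),
  a minimum-completeness positivity filter, sliding-window hot-spot
  selection (1000–2000 cells), and the composite score

  `DIA = %positive cells × avg positive membrane OD × avg positive membrane completeness`

- **`sstr2dia.scoring`** — Volante score, IRS, Ki-67 labeling index
  (truncated to 2 decimals, WHO-2019 counting), WHO grade (G1 < 3%,
  G2 3–20%, G3 > 20%), chromogranin-A double-stain positive rate.
- **`sstr2dia.stats`** — tie-aware Mann–Whitney AUC, empirical ROC with
  Youden-optimal cutoff, DeLong test for correlated AUCs, Wilcoxon
  rank-sum / Kruskal–Wallis / Spearman / χ² wrappers, Bonferroni correction.
- **`sstr2dia.fixtures`** — two embedded, checksum-verified case tables: 14
  SSA-treated GI-NET cases (three SSTR2 scores + RECIST response) and 37
  normal-mucosa specimens (SSTR2 positive rates of neuroendocrine cells in
  stomach/duodenum/rectum).
- **`sstr2dia.synthetic`** — generators for brightfield IHC images with
  exact per-cell ground truth (stains composed in OD space, so
  deconvolution is exactly invertible) and for cohort tables with
  controlled site-wise score–Ki-67 rank correlations.
- **`sstr2dia.pipeline`** / CLI `sstr2dia` — end-to-end reproduction
  analyses and synthetic validation.

## Worked example

```python
>>> from sstr2dia import reproduce_response_roc
>>> r = reproduce_response_roc()
>>> for name, s in r["scores"].items():
...     print(name, s["auc"], s["cutoff"], s["sensitivity"], s["specificity"])
dia 0.65 898.0 0.8 0.75
volante 0.6125 2.0 0.9 0.25
irs 0.5875 4.0 0.7 0.5
```

On the 14 SSA-treated cases (10 CR/SD responders vs 4 PD), the DIA
composite discriminates responders best (AUC 0.65) and is the only score
whose Youden cutoff balances sensitivity (80%) with specificity (75%);
the eyeball Volante score is sensitive (90%) but unspecific (25%). The
DeLong comparisons in `r["delong"]` are all non-significant after
Bonferroni correction — at n = 14 the three methods cannot be statistically
separated. `r["volante_positive_response_rate"]` is 75.0: three quarters of
Volante-positive (score ≥ 2) cases responded.

The synthetic round trip (`examples/04_synthetic_roundtrip.py`) prints:

```
cells: 150 rendered, 150 detected
% positive cells:      true  81.33  measured  81.33
mean positive OD:      true  0.443  measured  0.439
mean completeness (%): true  64.55  measured  65.89
composite score: 2354.3 (table form: 2354)
```

i.e. the pipeline recovers the generator's ground truth to within pixel
quantization and sensor noise. See `examples/` for runnable scripts covering
each capability.

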