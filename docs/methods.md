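# Methods

## The measurement problem

Membranous SSTR2 immunoreactivity is scored on brightfield slides stained
with DAB (brown, the SSTR2 signal) over a hematoxylin counterstain (blue,
nuclei). Eyeball scores compress a slide into a small ordinal value; the
digital pipeline instead measures every tumor cell and summarizes a
1000–2000-cell hot spot as

```
DIA = %positive cells × avg positive membrane OD × avg positive membrane completeness
```

with percentages on the 0–100 scale and optical density (OD) in
absorbance units, so scores on real material span roughly 0–2900. With all
three factors at their maxima (100 × 1.0 × 100) the score is bounded by
10,000. Reported table values are rounded *down* to integers.

## Color deconvolution

A pixel's per-channel OD is `−log10((I+ε)/255)` with `ε = 1` intensity
unit guarding `log 0` (and making a pixel at intensity 254 exactly OD 0).
Stain abundances come from inverting the 3×3 stain matrix whose rows are
the unit DAB vector (0.268, 0.570, 0.776), the unit hematoxylin vector
(0.650, 0.704, 0.286) and their normalized cross product as residual —
the standard Ruifrok–Johnston scheme. Matrix inversion rather than
projection is essential here: the two stain vectors have a dot product of
≈0.80, so projecting the OD vector onto the DAB axis alone would assign a
purely hematoxylin-stained nucleus (typical OD ≈ 0.5) a spurious DAB
signal of ≈0.4 — far above any sensible positivity threshold — whereas
unmixing returns ≈0 for it. Negative unmixed concentrations (noise) are
clamped to zero.

## Segmentation and membrane measurement

Nuclei are supra-threshold regions of the hematoxylin map (default OD
≥ 0.15) split by a watershed on the distance transform with markers at
least 10 px apart; nuclei closer than that merge deterministically.
Candidates outside the nuclear size bounds (20–500 px²) or below roundness
0.4 (4πA/P², capped at 1) are discarded. Each nucleus is expanded by 5 px
into a cell territory bounded by its neighbors; the membrane ring is the
outer 3-px band of the territory. Cells whose territory touches the image
border are measured on the clipped ring and flagged.

*Membrane completeness* is defined as angular coverage: the ring is divided
into 36 sectors of 10° about the nucleus centroid, and completeness is the
percentage of sectors containing at least one ring pixel with DAB OD at or
above the pixel positivity threshold (default 0.15, configurable — the
stain vector is standardized in the field but the threshold is not). The
mean membrane OD averages supra-threshold ring pixels only, and the
hot-spot summary averages per cell, not per pixel (the cell-averaged
reading of "average positive membrane completeness"; a pixel-weighted
variant would weight large cells more). A cell is *positive* when its
completeness **strictly** exceeds the minimum-completeness parameter;
the default of 0% therefore counts any cell with detectable membrane
signal, while a setting of 50% excludes cells at exactly 50%.

Hot spots are selected by sweeping a 512×512 window at stride 128 and
keeping the window with 1000–2000 cells whose cells maximize the composite
score; ties go to the smallest (row, col) origin, windows over capacity are
used only if no in-range window exists, and if no window reaches 1000
cells the whole image is used with a `degraded` flag (small fields are
valid input, just noisier).

## Manual scores and counting rules

- **Volante score**: 0 no staining, 1 purely cytoplasmic, 2 membranous but
  incomplete or in ≤50% of cells, 3 circumferential membranous in >50% of
  cells. The criteria triple (localization, extent, fraction) maps totally
  onto {0,1,2,3}.
- **IRS**: positivity bin (0: 0%, 1: <10%, 2: 10–50%, 3: 51–80%, 4: >80%) ×
  intensity (0–3); attainable values are exactly {0,1,2,3,4,6,8,9,12}.
  Fractions in (50, 51) fall in bin 3. The full 0–12 range is implemented
  (0 occurs whenever either factor is 0).
- **Ki-67 LI**: positive/total nuclei (≥500 expected; fewer warns) in
  percent, truncated — not rounded — to 2 decimals, computed in integer
  arithmetic so truncation is exact. WHO grade uses Ki-67 alone (G1 < 3%,
  G2 3–20% inclusive, G3 > 20%); mitotic counts are out of scope.
- **Double-stain positive rate**: SSTR2⁺/chromogranin-A⁺ cells over
  chromogranin-A⁺ cells, truncated to 4 decimals, with ≥10 denominator
  cells expected. The embedded mucosa table stores the printed 3-decimal
  values verbatim.

## Statistics

The AUC is the tie-aware Mann–Whitney statistic (ties count ½), which
equals the trapezoidal area under the empirical ROC for any tie pattern;
orientation is fixed as *score ≥ threshold ⇒ predicted responder*. Youden
cutoffs maximize sens + spec − 1 with ties broken toward higher
specificity, then the lower cutoff. The DeLong test estimates the variance
of a paired AUC difference from the empirical covariance of per-case
placement values and refers the statistic to a standard normal
(two-sided); its implementation is cross-checked in the test suite against
R's pROC on the embedded cohort and against a paired bootstrap. Two AUCs
that are numerically identical with zero estimated variance are reported
as p = 1; a zero variance with a real AUC difference raises. Wilcoxon
rank-sum defaults to the normal approximation with tie and continuity
corrections (continuity can be disabled; an exact method is available for
small untied samples) — published p-values from other software are
therefore matched in order of magnitude, not digit-for-digit.
Kruskal–Wallis is tie-corrected with an all-identical input defined as
p = 1. Bonferroni uses m = 3 for the three pairwise AUC comparisons and
m = 2 for the two mucosal-site contrasts.

## Synthetic data

The image generator places non-overlapping cells by rejection sampling
(explicit failure when the requested count cannot be packed), draws a
hematoxylin nucleus disk (radius 6 px, OD 0.5) and a DAB membrane annulus
(radii r+2 to r+5) covering a contiguous angular arc equal to the requested
completeness, starting at a seeded random phase. Stains are composed in OD
space and converted by `I = 255·10^(−OD)`, then Gaussian sensor noise
(σ = 2 intensity units) is added and the image quantized to 8 bits. Because
rendering and deconvolution share the OD model, the generator is an exact
oracle up to quantization: the pipeline recovers % positive cells to ~0
points, mean OD to ~1% and completeness to ~1 point on default fields
(documented tolerances: 5 points, 10%, 10 points). What the generator does
*not* emulate — tissue texture, stroma, overlapping nuclei, fixation and
scanner artifacts — means passing the round trip shows the measurement
contract is implemented correctly, not that segmentation would be accurate
on real slides.

The cohort generator defaults to the site mix of a resected GI-NET series
(56 foregut / 5 midgut / 71 hindgut), log-normal Ki-67 (median 1.8%,
log-σ 1.2, giving mostly G1 with a G3 tail), a uniform DIA marginal on
0–2900, score-derived Volante/IRS bins, and site-wise Spearman targets
−0.37 (foregut), +0.25 (midgut), +0.33 (hindgut). Rank correlation is
induced by mixing the Ki-67 latent with independent noise and solving the
mixing weight by bisection against the *realized* rank correlation of the
draw, so each generated site lands within ~0.02 of its target for n ≥ ~20
— comfortably inside the generator's ±0.15 contract — rather than
carrying O(1/√n) copula sampling noise. An optional logistic model on the
standardized DIA score generates binary response labels; slope 0 yields a
chance-level (AUC ≈ 0.5) score by construction.

## Problem sizes and determinism

The embedded-cohort analyses are pure arithmetic on 14 and 37 rows and use
no randomness. Synthetic validation uses a 512×512 field with 150 cells and
two 60-case cohort sites — large enough that the documented tolerances are
meaningful, small enough that the whole suite runs in seconds. All
randomness flows through explicit integer seeds; identical spec + seed
gives bit-identical images, tables and reports.

## Known limitations

- The HALO membrane algorithm this contract mirrors is proprietary; the
  angular-sector completeness operator and the cell-averaged summary are
  explicit, documented substitutes, so absolute composite values are
  comparable only within this implementation.
- The published DIA cutoff 898.945 arises from unrounded scores; on the
  embedded (floor-rounded) table the Youden cutoff reproduces as 898 with
  identical sensitivity/specificity.
- Segmentation parameters are tuned for the synthetic geometry (isolated,
  round nuclei) and would need re-tuning for real whole-slide material.
- Exact small-sample null distributions are provided only where the exact
  method is exposed (untied rank-sum); elsewhere asymptotic approximations
  are used, as in the original analyses.
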