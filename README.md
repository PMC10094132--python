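# dysquant

Spectral-confocal quantification of sarcolemmal dystrophin in transverse
muscle sections, for neuromuscular labs and methods researchers working on
Duchenne/Becker muscular dystrophy (DMD/BMD) diagnostics and
dystrophin-restoring therapy readouts.

Dystrophin loss is the hallmark of DMD (near-absent protein) and BMD
(reduced protein), and therapies aim at subtle increases — so intensities
must be quantified far below what conventional immunofluorescence resolves.
The approach implemented here images double-immunolabelled sections as
two-channel **x-y-λ stacks** (one 12-bit slice per emission-detection
window, e.g. 485–625 nm in 15 nm windows stepped by 5.21 nm) and quantifies
dystrophin only on the sarcolemma, inside small elliptical ROIs placed with
the β-spectrin channel as a membrane guide.

## Method

For a stack `I(r, c, k)` and an elliptical ROI `E` (pixel-centre
rasterization), the **spectral signature** is

```
S_E(λ_k) = mean over (r,c) in E of I(r, c, k)
```

The **emission peak** `k* = argmax_k mean_E S_E(λ_k)` is selected once on
the pooled mean signature (per biopsy by default), and each ROI contributes
the single value `S_E(λ_k*)`. A biopsy is summarised as mean ± SE over its
78 ROIs (3 fields × 26 ROIs).

**Automatic ROI detection** runs entirely on the guide channel: brightest
window → median filter → Otsu binarization (wall bright) → morphological
extraction of fibre interiors (opening, hole filling, area ≥ 300 px,
circularity ≥ 0.3) → sarcolemma band = dilated fibres minus fibres →
candidate ellipses along the band skeleton, oriented by the local wall
tangent → score

```
total = w_b · brightness + w_o · |cos(θ − θ_wall)| + w_w · max(0, 2·f_wall − 1)
```

(defaults `w = (1/3, 1/3, 1/3)`; `f_wall` = fraction of ROI pixels on the
band) → greedy selection of the best 26 non-overlapping candidates.
Selection never reads the dystrophin channel, so it is diagnosis-blind.

The statistical layer provides ICC(2,1) reproducibility (two-way random,
absolute agreement, single measures), Shapiro–Wilk normality,
Kruskal–Wallis + pairwise rank-sum group comparisons on raw ROI values, and
the pooled-variance t-test for manual-vs-automatic method equivalence.

Because no patient images are distributable, `dysquant.simulate` generates
synthetic fields with full ground truth: perturbed-Voronoi fibre packings
with a sarcolemma wall, vessel/adipose/connective confounders, Gaussian
emission spectra integrated over the overlapping detection windows, shot +
readout noise, and 12-bit quantization. Everything is seeded.

## Worked example

```
python examples/03_quantify_biopsy.py
```

prints (exact values are seed-dependent):

```
DMD-01: n=78 ROIs over 3 fields
emission peak at 521.5 nm (per_biopsy)
dystrophin: 442.3 ± 14.5 a.u. (generated at 500.8)
as a percentage of the control level: 14.8%
```

A severe-dystrophy biopsy simulated at a sarcolemmal level of 500.8 a.u.
is recovered from 78 automatically placed ROIs; the peak window (521.5 nm)
is the detection window nearest the fluorophore's 519 nm emission peak.
The recovered mean scatters around the generating level with the
between-fibre spread (ROIs on one fibre are correlated), so single-biopsy
deviations of a few percent are expected. Dividing by the control-group
mean expresses the result as a percentage of normal expression — the scale
on which trace amounts (0.5% of control ≈ 15 a.u.) are still detectable.

The other examples cover field simulation (`01`), automatic detection
against ground truth (`02`), cohort statistics (`04` — group means
separate DMD ≪ BMD ≪ control with Kruskal–Wallis p < 0.05), and
manual-vs-automatic equivalence plus ICC reproducibility (`05`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the pipeline-recovered 78-ROI mean peak intensity
of a 3-field synthetic biopsy generated at the published severe-dystrophy
level (target `t4`) and at the published control level (target `t5`),
using fully automatic ROI detection, and writes the recovered values (a.u.)
with the ROI counts to the given JSON path.
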