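# Methods

## The measurement model

A spectral confocal acquisition of a double-immunolabelled transverse muscle
section yields, per channel, an x-y-λ cube: 512×512 pixels (0.361 µm/px,
12-bit) by one slice per emission-detection window. Windows are 15 nm wide
and stepped by 5.21 nm, so they overlap; the dystrophin channel (AF488-like,
excited at 470 nm) is collected 485–625 nm (27 windows) and the β-spectrin
guide channel (Cy5-like, excited at 570 nm) 590–780 nm. The quantity of
interest is the mean dystrophin intensity at the maximum emission peak,
measured only on the sarcolemma inside small elliptical ROIs, averaged over
78 ROIs per biopsy (3 fields × 26).

Assumptions baked into the pipeline:

* the guide channel marks an intact sarcolemma brightly relative to
  sarcoplasm, so fibre interiors emerge as the complement of the bright
  class after binarization (this polarity is a design choice: "binarize"
  alone does not determine it, and no other choice yields fibre regions);
* acquisition gain/offset are constant within a field, so raw a.u. are
  comparable across ROIs and fields;
* one emission peak per antibody per biopsy: the peak window is selected on
  the mean signature pooled over all of a biopsy's ROIs, then every ROI is
  re-read at that window (`peak_policy="per_biopsy"`; a `per_field` option
  keeps each field's own peak). Pooling level is a reading of the protocol,
  recorded in the output metadata.

## Automatic ROI detection

Stages, all config-exposed (`PipelineConfig` / `DetectionConfig`):

1. **Reference slice** — argmax of per-window mean intensity; ties to the
   lowest index.
2. **Median filter** — (2r+1)² window, r = 1 px default, reflected edges.
3. **Binarization** — Otsu's between-class-variance threshold (`fixed`
   available); constant images raise instead of guessing.
4. **Fibre extraction** — on the complement of the bright mask: opening
   (disc r = 2 px), hole filling, optional border clearing, area ≥ 300 px
   (≈ 39 µm²), circularity 4πA/P² ≥ 0.3 (fibres are polygonal; a high
   floor would reject real fibres). Border clearing defaults to **off**:
   transverse sections tile the whole frame, so clearing border-touching
   components would discard roughly half the true fibres and cap recall far
   below the ≥ 90 % the pipeline achieves with it off.
5. **Sarcolemma band** — union of fibres dilated by 4 px minus the fibres;
   thickness = 2 × median distance-transform value on the band skeleton;
   per-pixel tangent from the structure tensor (σ = 3 px), as the minor
   eigenvector (direction of least variation).
6. **Candidates** — skeleton pixels kept in (row, col) order subject to a
   minimum spacing; ellipse size is tied to the measured wall:
   semi-minor = max(1, thickness/2), semi-major = 2 × semi-minor,
   spacing = 2 × semi-major. Small ellipses keep ROIs membrane-only.
7. **Scoring** — convex combination (default equal weights) of brightness
   (ROI mean / field max), tangent alignment |cos Δθ|, and wall overlap
   (in-fraction minus out-fraction, clipped to [0, 1]). The published
   description names the three criteria but no formula; the additive form
   with exposed weights is the minimal realization (a multiplicative form
   would also be consistent; only the additive one is implemented).
8. **Selection** — best-first greedy with exact rasterized-overlap
   rejection, ties broken by (row, col); stops at n = 26 or exhaustion
   (shortfall flagged).

The chain is deterministic and never touches the dystrophin channel.

## Quantification and statistics

ROI rasterization is exact pixel-centre-inside-ellipse; the ROI mean
spectrum equals the brute-force pixel loop by construction (tested).
Biopsy SE is computed over the pooled ROIs, matching the published
convention of SEs "over the 78 ROIs" — note this understates biopsy-level
uncertainty because ROIs on one fibre share that fibre's membrane
intensity; recovered single-biopsy means scatter with the between-fibre SD
divided by √(fibres sampled), a few percent at default settings.

ICC(2,1) (two-way random effects, absolute agreement, single measures) is
computed from ANOVA mean squares with the standard F-based 95 % CI; the
published account of replicate counts is ambiguous (four experiments vs
three replications), so raters = however many replicate columns are
supplied. "Wilcoxon" comparisons of unpaired raw values are implemented as
the rank-sum (Mann–Whitney) test; p-values are reported unadjusted to match
the published analysis, with optional Holm adjustment. Shapiro–Wilk,
Kruskal–Wallis, rank-sum and the pooled-variance t-test are delegated to
scipy.

## The synthetic generator

What it emulates: packed polygonal fibres (Voronoi cells of Poisson-disc
seeds on smoothly warped coordinates) separated by a ~4 px (≈ 1.4 µm) wall;
per-fibre wall intensities (between-ROI variability); dimmer sarcoplasm
(8 % of wall) and background (2 %); vessel/adipose/connective regions that
stay membrane-bright only in the guide channel; Gaussian emission lines
integrated over the overlapping windows and normalized so the brightest
window carries the nominal wall level; flat autofluorescence (5 a.u.);
optional linear bleed-through between channels (default 0); Gaussian shot
noise (variance = signal) plus 8 a.u. readout noise; 12-bit quantization
with a recorded warning when > 1 % of wall pixels would clip.

Intensity defaults are the published group levels: dystrophin wall means
per antibody and diagnosis (e.g. NCL-Dys1: 500.8 / 1190.8 / 2982.9 a.u. for
DMD / BMD / control) with between-ROI SD reconstructed as SE·√78 from the
published standard errors, which are explicitly tied to 78 ROIs. The
β-spectrin guide means (2346.13 / 2379.38 / 1832.17 a.u.) carry published
errors *not* tied to an ROI count; applying the √78 reconstruction there
would imply a 64 % between-fibre CV — implausible for a membrane-integrity
control and enough to render occasional wall segments at ~0, merging
fibres. The guide channel therefore uses a 10 % between-fibre CV. Fibre
count (~30 per 512 px field) and wall thickness are plausible defaults for
transverse sections at this magnification, not published facts. Cohorts
default to the published shape (10 DMD / 3 BMD / 6 control biopsies,
3 fields each) with 5 % between-biopsy CV.

What it does **not** emulate: optics (PSF, z-extent), photobleaching,
fibrosis texture, necrotic fibres, staining gradients, or mosaic carrier
expression. A green test therefore establishes that the pipeline recovers
known intensities from realistic geometry, spectra and noise — not that it
is robust to every histological artefact.

Determinism: every generator function takes a seed; cohorts derive
per-biopsy/per-field streams from `numpy` seed sequences, so identical
(parameters, seed) give bit-identical stacks.

## Numerical choices

* Coordinates: 0-based (row, col), origin top-left; ellipse θ from the +col
  axis toward +row, normalised to [0, π).
* Wavelength axes require even spacing within 1e-6 nm; argmax ties resolve
  to the lowest window.
* Otsu on a constant image, ICC on a constant matrix, and t-tests with zero
  pooled variance raise rather than return NaN.
* ICC CI in the perfect-agreement limit (zero residual and rater variance)
  collapses to the point estimate.
* Stack files: multi-page TIFF (uint16 containers for 12-bit data) plus a
  JSON sidecar for wavelength/excitation/pixel metadata; ROI sets as CSV
  (θ in radians, ≥ 6 decimals). ImageJ ROI archives are not read (the
  needed reader is not a dependency); CSV is the interchange format.
* The published pixel-size/field-of-view figures (0.361 µm "²", 184.52 µm
  "²" for 512 px) are mutually inconsistent as areas; both are recorded,
  pixel size is treated as a linear pitch, and nothing downstream depends
  on the resolution.

## Test-scale notes

The test suite's cohort fixtures use 320×320 px fields (~14 fibres) and the
placement-accuracy sweep 256×256, purely to keep the suite inside a desk
time budget; acceptance targets recomputed by `scripts/acceptance.py` use
the full 512×512 stated world. Scaling the frame changes sampling noise,
not the pipeline's behaviour.

## Known limitations

* Ranking weights and the additive score are a reconstruction; the original
  implementation's exact ranking is unpublished.
* The per-biopsy peak policy is one reading of "a single value for the
  maximum emission peak per case"; per-field is available but changes
  results only when noise moves the argmax between overlapping windows.
* Between-ROI SD reconstruction from printed SEs assumes independent ROIs,
  which the fibre-sharing correlation violates mildly.
* The simulator's confounders are geometric stand-ins; they test that ROI
  placement avoids non-sarcolemmal structure, not vessel-specific optics.
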