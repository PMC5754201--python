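# Methods

## The quantification problem

In the *Drosophila* larval CNS each neural stem cell (NSC, marked by
nuclear Deadpan) and its lineage becomes enclosed in an individual
membrane chamber built by cortex glia (membrane marker Nrv2::GFP), with
newborn neurons (nuclear ElaV) lying beneath the NSC. In an intact,
nutrition-stimulated niche the three markers therefore stratify along the
imaging axis of a confocal Z-stack: a dense glial membrane sheet (the
"top layer", just under the blood–brain barrier) peaks shallowest, NSC
nuclei next, neurons deepest. When chamber formation fails (starvation,
insulin-pathway perturbation) the stratification collapses and all three
signals peak at the same depth, and the amount of glial membrane per NSC
drops. `nichechart` turns these observations into numbers.

## Chamber organisation chart

For one specimen (one ventral nerve cord, VNC) the user supplies a
multi-channel stack with axes (z, y, x, c) and an X,Y bounding box that
excludes off-target signal such as tracheal GFP. For each channel the
mean intensity over the box is computed per slice, giving a curve
I_c(z). Each curve is scaled so its maximum is exactly 1 — the
quantity of interest is the depth *distribution* of a marker, not its
absolute brightness, and normalization makes channels with different
staining efficiencies comparable on one chart.

### Sub-slice peak localization

The peak of each curve is refined below the slice spacing by three-point
parabolic interpolation. With y₋, y₀, y₊ the curve values at the integer
argmax k and its neighbours, the vertex of the interpolating parabola is

    ẑ = k + (y₋ − y₊) / (2 (y₋ − 2 y₀ + y₊))

(the zero of the parabola's derivative). This is exact for locally
quadratic curves and accurate to a few hundredths of a slice for smooth
unimodal profiles of width σ ≥ 2 slices; the error decreases as the
profile widens. Numerical choices:

* **Tie-break**: the argmax is the lowest slice index among tied maxima.
  A consequence worth knowing: at an interior argmax chosen this way the
  stencil is always strictly concave (y₋ < y₀ and y₊ ≤ y₀), so the
  degenerate-curvature fallback in the code is defensive only.
* **Boundary peaks**: when the argmax is the first or last slice the
  three-point stencil does not exist; the integer position is kept and
  the estimate is flagged unrefined. No extrapolation is attempted.
* **No smoothing** is applied before peak-finding; the refinement is
  scale-invariant, so raw and normalized curves give identical peaks.
* An all-zero curve is an explicit "empty channel" condition; the chart
  is still built for the remaining channels with the empty role flagged.

The per-specimen statistics compared across conditions are the **peak
offsets**: NSC peak depth minus glial peak depth, and neuron peak depth
minus glial peak depth, in slice units (positive = deeper than the glial
top layer). One offset pair per VNC; condition-level inference happens
downstream. Depths are reported in slice units; the Z spacing is carried
so µm conversion is possible, and mixing specimens with different
spacings in one comparison is the user's responsibility (the spacing is
recorded in every chart).

## Morphometrics

* **Membrane intensity** — the sum of glial-channel voxel intensities at
  or above a threshold, within the ROI, over all slices. "Total
  intensity" is interpreted as an intensity sum, not a voxel count; the
  count variant exists as `statistic="count"` for sensitivity analysis.
  An optional constant background offset can be subtracted before
  thresholding (off by default).
* **Membrane/NSC ratio** — membrane intensity divided by the NSC count;
  the proxy for per-lineage glial membrane abundance. Undefined (error)
  at zero NSCs.
* **Nucleus counting** — 26-connected components of the supra-threshold
  mask, with a minimum-volume filter to reject speckle. Touching nuclei
  merge into one component; this is a documented limitation (no
  watershed splitting), and manual counts can be supplied via CSV
  (`specimen_id, marker, count`) to override the automated count.
* **Neuronal volume** — supra-threshold neuron-channel voxel count
  (times voxel volume when spacing is known), normalized by dividing
  every specimen's value by the mean of the control group, centring the
  control mean at exactly 1.
* **Threshold policies** — absolute intensity, intensity quantile, or
  Otsu. A policy is resolved to one absolute threshold per role per
  experiment and then applied identically to every condition being
  compared; resolved values are recorded in the outputs.

## Statistics

Group comparisons use the classical equal-variance (pooled) two-sample
Student's t-test, two-sided, df = n_a + n_b − 2 (Welch's correction is
available as `equal_var=False` but is not the default). A
summary-statistics variant (`t_test_from_stats`) computes the same test
from group means and standard deviations. Group summaries report mean ±
SEM (sample sd / √n; undefined and flagged at n = 1) for bar graphs and
the five-number summary (minimum, Q1, median, Q3, maximum; quartiles by
linear interpolation between order statistics) for whisker plots.

The default significance-star convention is deliberately nonstandard:
`***` for p < 0.05, `*` for 0.05 ≤ p < 0.1, `ns` otherwise. It
reproduces the reporting convention of the study this pipeline
re-implements; the conventional `*/**/***` scheme is available as
`STANDARD_CONVENTION`. No multiple-testing correction is applied by
default. Degenerate inputs: two constant samples with equal means give
t = 0, p = 1; with unequal means the result is ±∞, p = 0 and flagged.

## Synthetic scenes

The generator renders three-channel stacks emulating the two niche
architectures:

* **fed** — glial channel: a horizontal membrane sheet with Gaussian
  z-profile (σ = 1.2 slices) centred at the top-layer depth, plus a
  chequerboard of vertical 1-pixel chamber walls (grid pitch 12 px,
  thinned to the configured coverage density, amplitude 0.4× the sheet)
  descending to the bottom of the neuron band. NSC channel: spheres
  (r = 4 voxels) in a band beneath the sheet; neuron channel: spheres
  (r = 3) in a deeper band. At the default shape (30, 128, 128):
  sheet at slice 8, NSC band 11–14, neuron band 16–24, wall density
  0.7, 12 NSCs, 40 neurons, all amplitudes 1.
* **starved** — sheet, NSC band (±1 slice) and neuron band (±1 slice)
  all centred at slice 12.5; wall density 0.1; membrane amplitude 0.45.
* **intermediate** — partial walls (0.4), membrane amplitude 0.7,
  NSC/neuron bands closer together.

Object depths are drawn from a triangular density peaked at the band
centre (in-plane positions uniform, with rejection of overlaps at
2r + 2 separation). Uniform depth placement would make a populated band
contribute a flat-topped plateau to the depth profile; the scenes being
emulated show a *peak* per population, and a plateau's maximum is not a
well-defined quantity to recover.

Rendering order: clean geometry → isotropic Gaussian blur (default
σ = 0.7 voxels) → additive Gaussian noise (default sd 0.05, ~5% of the
nuclear amplitude) clipped at zero. Additive Gaussian noise is a
deliberate simplification of microscope shot noise; the noise model is
confined to one code site and pluggable. All randomness flows from one
seed; scenes are bit-reproducible.

**Ground truth.** True peak depths are defined on the *expected image* —
the clean geometry after the configured blur, before noise — as the
dense-grid argmax of a cubic-spline interpolation of its depth profile.
The spline is independent of the pipeline's parabolic estimator, and the
expected image is deterministic given the placed geometry, so noise is
the only deviation a measurement must overcome. True counts are the
placed object numbers; the true glial integrated intensity is the masked
sum over the clean (pre-blur, pre-noise) render at a threshold recorded
in the ground-truth object. For non-default shapes the preset depth
bands scale linearly with slice count and object counts with plane area
(with floors of 4 NSCs / 10 neurons to keep profiles stable); shapes
below (24, 64, 64), or too shallow to separate the band centres by 3
slices, are rejected.

An optional `trachea` flag adds a bright off-target tube to the glial
channel at the image margin, to exercise the ROI mechanism that real
analyses need.

### What the generator does and does not emulate

It reproduces the *geometry* of the niche readouts — depth stratification
versus collapse, membrane abundance differences, countable nuclei — with
plausible SNR. It does not model real optics (no PSF anisotropy),
Poisson photon statistics, bleaching, depth-dependent attenuation,
nucleus shape variation, or touching-nucleus clumps beyond the explicit
overlap test case. Passing recovery tests on these scenes therefore
demonstrates correctness of the measurement code, not robustness to
every pathology of real confocal data; thresholds for real experiments
must still be chosen against real staining.

## Problem sizes

Recovery sweeps use 20 scenes of shape (30, 96, 96) per preset; cohort
power checks use 100 replicate pairs of 6-specimen arms at (28, 64, 64).
These sizes give the effect-direction and rejection-rate estimates ~1%
resolution while keeping the whole verification run under a minute on
one CPU; the signature effects are large enough (ratio fold-change ≈
2.8, NSC offset ≈ +4 slices) that results are insensitive to the exact
shape used.

## Known limitations

* Connected-component counting undercounts touching nuclei (no
  watershed); supply manual counts where this matters.
* Peak offsets are in slice units; cross-specimen comparability assumes
  equal Z spacing.
* The membrane/NSC ratio performs no background subtraction by default;
  an additive offset option exists but flat-field correction does not.
* The chart is a 1D depth summary by design; it does not segment
  chambers in 2D/3D.
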