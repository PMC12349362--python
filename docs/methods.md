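# Methods

This note documents the models, conventions and parameter choices behind
the package, and what the synthetic-data tests do and do not demonstrate
about real fruit sections.

## Rugosity index and level classification

The rugosity index of one slice is
`RI (%) = (epidermal length − section length) / section length × 100`,
with the epidermal length measured as the Euclidean length of the traced
polyline in input order (no smoothing or resampling is applied at this
stage; preprocessing belongs to the image-extraction step). Two section-
length conventions are supported:

* **nominal** (default): the excised section length, 30 mm. This matches a
  protocol in which a 3 cm section is cut and the whole contour traced.
* **chord**: the endpoint-to-endpoint distance of the traced contour, for
  imperfect excisions. In chord mode RI is invariant under rigid motions
  and global rescaling of the contour.

A fruit's RI is the arithmetic mean over its slices (four expected; other
counts are accepted with a warning). Levels use left-closed, right-open
intervals with boundaries 1.5 / 2.5 / 3.5 %: `[0,1.5) → 1, [1.5,2.5) → 2,
[2.5,3.5) → 3, [3.5,∞) → 4`. The published interval notation is ambiguous
at the boundaries; left-closed intervals make the top level the only
unbounded class and classify every value exactly once. Slightly negative RI
(possible when tracing noise shortens the polyline below the section
length) is reported as-is with a warning and clamped to zero only for
classification, preserving the raw measurement.

## Synthetic profiles and the quadrature oracle

The canonical synthetic epidermis is a sinusoid `y = A sin(2πx/λ + φ)` over
a 30 mm section, chosen because its arc length has an independent oracle:
adaptive Gauss–Kronrod quadrature of `∫√(1 + y′²) dx` (relative tolerance
1e−9, one panel per wavelength), cross-checked in the tests against dense
trapezoidal integration and against the small-slope closed form
`RI → 100·π²A²/λ²`. A multi-harmonic composite profile stresses the same
machinery on non-sinusoidal shapes. Gaussian noise is added to y only, so
profiles remain graph-like and the chord stays equal to the section length.
Sampled polylines converge to the quadrature arc length from below as the
spacing shrinks (chords never exceed arcs), which the suite checks
explicitly.

## Image rendering and contour extraction

Rendered sections are binary bands whose upper boundary is the contour,
with pixel centres on the grid `j/px_per_mm` and a 1 mm background margin
above the crest. Extraction walks the uppermost tissue pixel of each column
(the boundary estimate is the first tissue row minus half a pixel, an
unbiased estimator under uniform sub-pixel phase), fills gaps up to a
configurable width by linear interpolation, flips y so larger values point
outward, smooths, and resamples uniformly in arc length (default spacing
0.1 mm).

Smoothing controls the coastline effect: raw pixel quantisation inflates
polyline length, and the inflation grows with resolution unless suppressed.
The default smoother is a **Savitzky–Golay local quartic over a 0.5 mm
window**. A plain moving average over the same window attenuates a ridge of
wavelength λ by sinc(πw/λ); on strongly wavy profiles (RI ≈ 6 %, λ = 5 mm)
this biases RI downward by ≈ 0.3–0.4 percentage points regardless of
resolution, so the round-trip error would be dominated by a constant
smoothing artefact rather than by the image itself. The quartic local fit
attenuates only at sixth order in w/λ, leaving the residual round-trip
error quantisation-dominated: measured max |RI error| over true RI ∈ [0,6]%
falls from ≈ 0.6 points at 20 px/mm to ≈ 0.07 at 40 px/mm and ≈ 0.014 at
80 px/mm, decreasing with resolution as a measurement error should. The
boxcar remains available (`method="moving_average"`) and its attenuation is
itself used as a test oracle (RI decreases monotonically with window
width). Both window and spacing are configurable; manual tracing implicitly
smooths, and no published tracing resolution exists to match, so these
defaults are a stand-in calibrated to ridge wavelengths of a few mm and
resolutions ≥ 20 px/mm.

## Synthetic population

Each fruit draws a true level from configurable proportions (default
0.2/0.3/0.3/0.2), an RI from a truncated normal confined to its level's
interval (level 4 capped at 8 %), a sensory grade equal to the true level
except with probability *q* a neighbouring level, and indicator values
`mean(level) + Gaussian noise`. Default level means plant the qualitative
pattern of interest: rupture force (65.5, 40, 22, 10 — a 6.55-fold
level-1/level-4 ratio), hardness, adhesiveness and chewiness decreasing;
shear force flat; β-galactosidase, polygalacturonase and ionically soluble
pectin increasing; remaining cell-wall fractions and enzymes flat.

Because RI and sensory grade are conditionally independent given the true
level, the population R² of the sensory-on-RI regression has a closed form
in the level proportions, truncated-normal moments and misgrade kernel;
`calibrate_sensory_misgrade(target_r2)` inverts it by root finding. The
default misgrade probability (0.25) is a free parameter — the misgrading
structure of real sensory panels is unknown — and analyses that need a
specific correlation regime should calibrate explicitly.

What the generator does **not** emulate: measurement correlations between
indicators beyond their shared level dependence, level-dependent indicator
variances, genetic structure (no marker data, no segregation distortion),
or any real F2 phenotype values, which are unpublished. Passing tests
therefore demonstrate correctness of the estimators and calibration of the
statistics under a plausible population model, not agreement with any
particular field dataset.

## Counts, differential expression and modules

Counts follow a negative-binomial model with log-normal gene abundances,
gene-wise dispersion (default 0.05, log-normal jitter ×exp(N(0, 0.25))),
per-sample library sizes ≈ 10⁶ (±15 % uniform), and expected counts
renormalised per sample so the matrix is compositional like real
sequencing data. Planted DE genes (alternating up/down at the configured
log2 fold change, applied to the rugose genotype at all stages) are drawn
from at least median abundance, so planted effects are not confounded with
detection-limit noise — mirroring the practice of validating moderately to
highly expressed candidates.

The DE test is deliberately simple: median-of-ratios size factors, pooled
two-sample t on log2(normalised + 1), effect reported as
log2((mean_a + 1)/(mean_b + 1)). Its contract is (i) approximately uniform
p-values under the null (checked by Kolmogorov–Smirnov), (ii) ≤ 2 % of
genes passing the DEG filter on null data, and (iii) high power on strong
planted effects (≥ 45/50 at log2FC 4 on the 9-vs-9 genotype contrast). It
is **not** an edgeR/DESeq2 reimplementation and will not reproduce their
per-gene statistics; with only three replicates per condition its
stage-matched 3-vs-3 power at low counts is materially below that of
moderated-variance engines. The DEG filter itself is exact:
pass ⇔ |log2FC| ≥ log2(2) (inclusive) and BH-adjusted q < 0.01 (strict).
BH adjustment is the standard step-up rule, hand-implemented and tested for
exact agreement with an independent implementation.

K-means modules are computed on standardized (mean 0, SD 1 per gene,
population SD) group-mean profiles over the six genotype × stage groups —
matching co-expression displays whose x-axis is the six conditions — with
Euclidean distance, 25 restarts and a required seed; module profiles are
recomputed as member means rather than taken from the solver. k is a free
parameter (published analyses used values yielding 11 and 16 modules on
different gene sets); no selection rule is implied. Sample PCA runs on
log2(FPKM + 1) with gene centring. FPKM uses the in-matrix column sum as
the per-sample mapped-read total, a documented convention since aligner
totals are unavailable downstream.

## 2^−ΔΔCt

Technical replicates are averaged on the Ct scale first; then
ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt(sample) − ΔCt(calibrator), and
relative expression is 2^−ΔΔCt. With noise-free Ct tables the generator's
configured log2 ratios are recovered exactly (to floating point); with
0.2-cycle technical noise and three replicates the mean absolute log2
recovery error is below 0.25.

## Numerical choices and degenerate inputs

* Contours require ≥ 2 distinct finite points; order is never changed.
* Classification of non-finite RI raises; negative RI clamps with warning.
* Tukey HSD uses the studentized range with the Tukey–Kramer unequal-n
  adjustment (statsmodels); the compact letter display uses
  insert-and-absorb with groups ordered by descending mean, which makes the
  lettering deterministic and guarantees letters are consistent with the
  adjusted-p matrix in both directions.
* The t-test on two identical constant groups returns t = 0, p = 1; unequal
  constant groups raise a degenerate-design error.
* Correlation pairs need ≥ 3 complete rows; constant columns yield missing
  r with a warning. Star thresholds 0.05/0.01/0.001, no multiplicity
  correction across the matrix.
* Pseudocount 1 in all log transforms; zero-count columns raise rather than
  silently producing infinities.
* All generators are bit-reproducible given a seed; K-means and the CLI
  require seeds explicitly.

## Problem sizes

The validation suite runs at desk scale, chosen to give stable statistics
while keeping the whole suite fast: 2000-gene × 18-sample matrices, 2000
null ANOVA simulations, 500 population seeds at n = 277, 1000 random
p-vectors for the BH cross-check, and image round trips at 20/40/80 px/mm
over seven RI values. These sizes are package defaults, and all of them are
parameters.

## Known limitations

* Real section images contain illumination gradients, debris and partial
  occlusion; the extraction pipeline assumes a single connected tissue band
  with a traceable upper boundary and at most small column gaps.
* Headline empirical values from any particular study (a specific R², DEG
  count, module count or PC1 fraction) depend on unpublished raw data and
  on the exact DE engine, and are out of scope; the package reproduces the
  *procedures* and validates them on ground-truth synthetics.
* The sensory process is modelled as neighbour misgrading only; real panels
  may skip levels or be biased asymmetrically.
* FPKM is within-sample normalisation only and is not used for
  cross-sample testing (the DE path normalises counts directly).
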