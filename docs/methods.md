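# Methods

`shellproxy` implements a quantitative temperature proxy for the
crossed-acicular (CA) shell microstructure of *Arctica islandica*: SEM
backscatter images of the hinge plate are segmented into biomineral units
(BMUs) and pores, per-entity morphometrics are computed, and the sizes of the
largest entities per culturing-temperature group are calibrated against water
temperature.  Laboratory-grown shell zones are discriminated from field-grown
material by changepoint detection on Mn/Ca transects.  This note records the
model, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## The proxy model

The central empirical structure is an asymmetric response of entity sizes to
temperature: the overwhelming majority of BMUs and pores are small and
temperature-invariant (a cut-effect of sectioning needle-shaped crystallites
at arbitrary angles, plus biological limitation), while only the upper tail of
the size distribution scales with temperature.  Consequently:

* whole distributions are compared with two-sample Kolmogorov–Smirnov tests
  on ECDFs of entity size;
* calibration uses the **15 largest** entities per temperature group, pooled
  across the group's specimens (`top_n`, default N = 15).  The
  `threshold_sensitivity` curve makes the reasoning measurable: Spearman's r
  between pooled top-N size and temperature decays as N grows into the
  invariant bulk;
* BMU size is calibrated linearly, `S = α + βT`, by ordinary least squares;
  pore size exponentially, `S = a·exp(bT)`, by nonlinear least squares
  initialized from the log-linear regression.  The exponential form is
  preferred for pores because linear fits predict negative sizes near 0 °C
  and leave non-randomly distributed residuals; both failure modes are
  computed as diagnostics (sign-runs test on residuals and a negativity check
  of predictions on the 0–16 °C grid) rather than judged by eye.
* a second, model-free statistic is the **coverage**: the percentage of
  pixels brighter than the mean gray value of the image batch.  Gray value is
  read as surface height (after H₂O₂ oxidation the biomineral plateaus stand
  out of the surface), so coverage is a lower bound on the areal fraction of
  crystalline phase.

Both the regression R² and the rank statistics (Spearman r and its square)
are reported side by side in `CalibrationModel`: squaring a rank correlation
and the least-squares goodness-of-fit answer different questions, and the two
need not agree.

Inverse prediction (`predict_temperature`) inverts the fitted curve and
propagates the ±2 SE parameter band numerically; estimates outside the
calibrated 1–15 °C range carry an extrapolation flag.

## Segmentation

Two routes, matching the two statistics:

* **Pixel classification** for per-entity masks: a random forest (100 trees,
  seedable) on a multi-scale feature bank — raw intensity plus, at each scale
  σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0} px: Gaussian-smoothed intensity, gradient
  magnitude, Laplacian-of-Gaussian, largest structure-tensor eigenvalue,
  largest Hessian eigenvalue (26 features).  Borders are reflected.  The
  truncated LoG kernel has a small DC response; it is subtracted so constant
  images yield exactly zero.  Training uses sparse user-style labels with at
  least 10 connected label regions per class per image (fewer is an error);
  held-out quality is reported as out-of-bag accuracy.
* **Mean-gray thresholding** for coverage: one global threshold, the mean
  intensity pooled over all images of a batch.  A pixel is white iff its
  intensity is *strictly greater* than the threshold; ties go to black, so a
  constant image has zero coverage.  The batch mean is computed with
  compensated (exact) summation so this tie contract does not depend on
  accumulation rounding.  A per-image mode exists behind a flag: the source
  procedure is worded both ways (per analysis set and across all studied
  images), and batch mode is the default.

## Morphometry

Connected components use 8-connectivity by default (standard for bright
blobs; configurable).  Area is pixel count × pixel area, always reported in
both units.  Elongation is the major/minor axis ratio of the
second-central-moment equivalent ellipse (eigenvalues of the pixel-coordinate
covariance), which is stable on small irregular components; a Feret
(minimum-rotated-rectangle caliper) mode is available for sensitivity checks.
Degenerate (collinear) components get their pixel count as a length/width
proxy and a `degenerate_moments` flag.  Components of fewer than 3 pixels
("larger than two pixels", strict reading; configurable) and components
touching the exclusion mask (fractures, dirt, scratches) are dropped, with
counts logged.  Touching entities are *not* split: CA BMUs genuinely merge,
and watershed splitting is out of scope.

## Mn/Ca zoning

Transects are split at the single changepoint minimizing the summed L1
deviations of both segments from their medians — a robust binary-segmentation
cost, invariant to rescaling the series, chosen because the field-zone Mn/Ca
distribution is heavy-tailed (inner-quartile range of the same order as the
median).  Exactly one changepoint is searched: the culturing experiment
defines one transition.  A split whose downstream median does not decrease is
flagged `no_lab_zone_signature`.  Zone levels are summarized as median ± one
inner-quartile range, pooled across specimens by default (a per-specimen
averaging mode exists; the pooling convention of the printed values is not
stated in the source).

## Synthetic data: what it emulates, and what it does not

The generator (`SyntheticConfig`, `generate_microstructure_image`) renders
per-pixel ground truth alongside each image, so every downstream stage is
testable without real micrographs.

Emulated:

* **BMU size mixture** — bulk lognormal (median ≈ 0.003 μm², log-sd 1.0),
  temperature-invariant, near the 2-pixel detection limit at the default
  0.0003 μm²/px; plus a sparse "large" component whose median scales linearly
  with temperature, `2.2 + 0.55·T` μm² (≈ 2.75 μm² at 1 °C to ≈ 10.45 μm² at
  15 °C, matching the observed top-15 group means).
* **Pore size mixture** — bulk lognormal (median 0.01 μm²); large component
  scaling exponentially at 0.193 /°C from a 0.56 μm² base (≈ 0.68 μm² at 1 °C,
  ≈ 10 μm² at 15 °C, the observed endpoint means; the rate is the closed-form
  two-point solve through those endpoints).
* **Geometry** — BMUs are needle-like ellipses (median elongation 2.5) in two
  dip modes at ±35° ± 8° off the growth front (image vertical; growth runs
  horizontal); pores are elongated parallel to the growth front (±6°).
* **Imaging** — topography as intensity (plateau 0.85 / rim 0.45 / background
  0.15 / pore 0.04), Gaussian noise (σ = 0.03), Poisson-distributed bright
  scratches and dark dirt blobs with a ground-truth artifact mask, and
  quantization to the 16-bit grid so a TIFF write/read roundtrip is lossless.
* **Mn/Ca transects** — two-level series with multiplicative lognormal noise
  (median-preserving) and a recorded true changepoint.

The `tail_fraction` default (0.012) is sized so that a temperature group of
three specimens carries ≈ 26–29 large entities in expectation — comfortably
more than the top-15 subset.  This mirrors the study condition that the 15
largest entities per group all belong to the temperature-scaled component (in
the culturing data the top-15 subsets contain no bulk-sized members), and it
is what makes N = 15 the meaningful subset size at this canvas scale.

Not emulated: photorealistic SEM texture, etching chemistry, 3-D
microstructure, curved growth fronts, entity fusion (placement enforces a
1-pixel separation margin so ground-truth components stay distinct), and
specimen-to-specimen imaging drift (brightness/contrast are calibrated away
in the real workflow).  Passing end-to-end tests therefore demonstrates that
the *computational* pipeline recovers encoded effects at realistic noise and
occupancy — not that segmentation of real CA micrographs reaches the same
accuracy.

Rasterization: entities are drawn as rotated ellipses with an iterative size
correction; rendered pixel areas match intended areas within 15% for entities
of ≥ 10 px, and placements clipped at the canvas border beyond that tolerance
are retried elsewhere.  All generators are pure functions of
`(config, seed)` — identical inputs give bit-identical rasters, which is what
makes the CLI's byte-identical rerun guarantee possible.

## Problem sizes and numerical choices

The default experiment is 3 specimens × 6 temperatures (1, 3, 6, 9, 12,
15 °C) on a 1280 × 1280 px canvas (≈ 491 μm² at 0.0003 μm²/px) with 800 BMUs
and 1.5 pores/μm² per image — chosen as the smallest canvas at which the
top-15 statistics sit safely inside the scaled tail while expected entity
occupancy stays below the generator's 60% precondition at 15 °C.  Classifier
training uses one labeled image (middle temperature level) per target, 12
label regions per class.  Parameter-recovery medians use 50 sampling-level
replicates of the same design; the imaged end-to-end run is scored once per
seed.  Quantile definitions: ECDF quantiles are order statistics
(`x_(ceil(p·n))`); inner-quartile range is `q75 − q25` with linear
interpolation.  Spearman p-values are two-sided asymptotic with average ranks
for ties; no multiple-testing correction is applied.  Nominal temperatures
are used for ranks (measured tank means change nothing: ranks are identical).

## Known limitations

* The pixel classifier is trained and evaluated on synthetic contrast; real
  backscatter images carry correlated noise, charging and polishing artifacts
  the generator does not model.
* The coverage statistic is threshold-relative by construction and is a
  lower bound, not an areal fraction; only its differences across conditions
  are meaningful.
* The changepoint search assumes exactly one transition and a decrease;
  transects with drift inside a zone can bias the split by a spot or two.
* Elongation of heavily merged entities reflects the merged component, not
  its constituent needles.
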