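# shellproxy

Quantitative temperature proxies from SEM backscatter images of bivalve shell
microstructure.

Bivalve shells are high-resolution climate archives, but the standard
geochemical thermometer (δ¹⁸O) needs the water's isotopic signature and is
vulnerable to diagenesis.  In the crossed-acicular (CA) microstructure of the
*Arctica islandica* hinge plate, the **size of the largest biomineral units
(BMUs)**, the **size of the largest pores**, and the **fraction of shell
covered by crystalline phase** all increase with water temperature — a
microstructural proxy that survives where geochemistry fails.  `shellproxy`
implements the complete computational workflow for this proxy, for
sclerochronologists and biomineralization researchers: machine-learning pixel
segmentation of SEM images, particle morphometry, distributional statistics,
calibration models, Mn/Ca-based discrimination of laboratory-grown shell
zones — plus a synthetic-image generator with exact ground truth so the whole
pipeline is testable end to end without micrographs.

## The model

Only the upper tail of the entity-size distribution carries the temperature
signal; the bulk is invariant.  The pipeline therefore:

- compares whole size distributions between temperature groups with
  two-sample Kolmogorov–Smirnov tests on ECDFs, `D = sup|F_a − F_b|`;
- calibrates on the pooled **N = 15 largest** entities per temperature group:
  linear `S = α + βT` for BMU size (OLS), exponential `S = a·e^{bT}` for pore
  size (nonlinear least squares, log-linear initialization), each with
  parameter standard errors, ±2 SE bands, Spearman's r, and residual
  diagnostics (sign-runs test, negativity of predictions on 0–16 °C);
- measures **BMU coverage** as the percentage of pixels strictly brighter
  than the mean gray value of the image batch (gray value read as surface
  height after H₂O₂ etching);
- inverts fitted models to predict temperature from measured sizes, with an
  extrapolation flag outside the calibrated 1–15 °C range;
- splits Mn/Ca transects into field/laboratory zones at the single
  changepoint minimizing a robust (median/L1) segmentation cost, and
  summarizes zones as median ± one inner-quartile range.

Segmentation is a seedable 100-tree random forest over a 26-feature
multi-scale bank (intensity, gradients, Laplacian-of-Gaussian, structure
tensor, Hessian at σ ∈ {0.7, 1.0, 1.6, 3.5, 5} px), trained from sparse
labels (≥ 10 regions per class per image).  See `docs/methods.md` for the
full model description and design rationale.

## Worked example

```python
import shellproxy as sp

# a synthetic specimen grown at 12 °C, with exact ground truth
cfg = sp.SyntheticConfig(temperature=12.0, seed=4)
image, truth = sp.generate_microstructure_image(cfg)

# train a pixel classifier from sparse user-style labels, segment, measure
labels = sp.sparse_labels_from_truth(truth, kind="BMU", n_regions=12, seed=4)
clf = sp.train_pixel_classifier([image], [labels], seed=0)
mask = sp.predict_mask(clf, image)
labeled, n = sp.label_components(mask)
records = sp.measure_particles(labeled, cfg.pixel_area,
                               exclusion=truth.artifact_mask,
                               kind="BMU", specimen_id="demo", temperature=12.0)
masks, thr = sp.binarize_mean_threshold([image])

print(f"{n} components, {len(records)} BMUs measured")
print(f"largest BMU: {max(r.area for r in records):.2f} um^2")
print(f"coverage at mean-gray threshold {thr:.3f}: {sp.coverage(masks[0]):.1f}%")
```

prints

```
437 components, 402 BMUs measured
largest BMU: 15.20 um^2
coverage at mean-gray threshold 0.368: 33.3%
```

The largest measured BMU (15.2 μm² at 12 °C) sits in the temperature-scaled
tail of the size distribution; the coverage value is the share of pixels
above the batch-mean gray level — a lower bound on the crystalline areal
fraction, meaningful in comparisons across temperatures.  Calibrating the
pooled top-15 sizes of a full six-temperature ladder (1–15 °C, three
specimens each) recovers the encoded effects:

```python
rep = sp.truth_calibration_replicate(seed=1)
# top-15 BMU size vs temperature: Spearman r = 0.97
# fitted pore rate b = 0.208 /C   (configured 0.193)
```

The same stages are available as CLI subcommands (`shellproxy simulate |
segment | measure | coverage | stats | calibrate | zones`); reruns with the
same configuration and seed produce byte-identical outputs.

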