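# Methods

## Model and procedure

`mvquant` treats microvessel quantification as supervised pixel
classification followed by thresholded area measurement.

**Pixel features.** Every pixel of the 8-bit grayscale image is described by
a fixed multi-scale stack: raw intensity; Gaussian-smoothed intensity,
Gaussian gradient magnitude at each scale σ ∈ {1, 2, 4, 8} px;
difference of Gaussians for consecutive scale pairs; and min, max, mean and
variance over a (2⌈σ⌉+1)² square window at each scale — 28 features at the
defaults. Borders use reflect padding. The small scales respond to
capillary-sized blobs; the large scales tell an isolated dark disc (which
brightens under heavy smoothing) from the interior of a perimysial
agglomerate (which stays dark), which is what separates class 2 from class 3
when their staining intensity is identical. Features are computed on the
grayscale image only; colour is deliberately discarded at stage one.
The scale list is configurable; train and predict share one configuration
recorded in the model file, and loading refuses a mismatch.

**Supervision.** Training labels come from rotated elliptical ROIs, each
assigned to background (1), isolated microvessel (2) or agglomerate (3).
A pixel belongs to an ellipse when its centre (array index coordinates) lies
strictly inside it; ellipses of one class pool and deduplicate their pixels,
while a pixel claimed by two different classes is dropped with a warning —
ambiguous supervision is worse than less supervision. Training requires at
least one pixel of every class.

**Classifier.** A random forest (default 200 trees, unlimited depth,
⌈√d⌉ features per split, bootstrap resampling, fixed seed) is fitted to the
labelled pixels; the engine is scikit-learn's `RandomForestClassifier`
behind the `PixelForestClassifier` estimator surface. Posteriors are soft
votes (averaged leaf class frequencies), rendered per class as an 8-bit
"probabilistic map" via round(255·p) with halves rounding up. By
construction the three class maps sum to 1 at every pixel. The
`learning_curve` helper grows one tree sequence incrementally (warm start)
so each requested ensemble size is a prefix of the next, and records
precision, recall, F-measure, fallout and the separation statistic
T = recall − fallout on evaluation pixels that are verified disjoint from
the training pixels (shared (image, pixel) keys raise a leakage error).

**Quantification and decision.** The class-2 map is filtered with inclusive
8-bit bounds, default [45, 255] (matching the manual counting procedure's
threshold so the two approaches are comparable; 255 is retained because
white is the highest posterior). The density statistic is
100·retained/total over all pixels of the image — slide background is not
excluded from the denominator; a tissue-mask denominator would be an
extension and is deliberately not the default. The screening rule flags an
image when its percent area strictly exceeds 4.0%. A mean-intensity gate
(default [40, 250]) skips under- or over-exposed images before
classification, since very dark inputs make the classifier unreliable; the
gate floor keeps the stage-6 filter floor of 45 meaningful.

**Agreement with manual counts.** `agreement` regresses manual measurements
on automated ones by ordinary least squares (scipy), reporting slope,
intercept, r², and the F statistic on (1, n−2) degrees of freedom with its
p-value. The automated value is the predictor because the use case is
predicting the manual ground truth; both directions give the same r².

## Synthetic data: what it emulates, and what it does not

The generator renders brightfield-IHC-like geometry on an 8-bit canvas
(default 512×512): background N(230, 3); isolated discs of radius 2–4 px
and multi-disc agglomerates (3 clusters of 6 overlapping blobs, radius
≈ 7–12 px) both at stain intensity N(70, 8) per structure; global pixel
noise N(0, 5); values clipped to [0, 255]. Classes 2 and 3 share the same
intensity distribution on purpose, so only morphology separates them —
the discriminative burden the real task places on the classifier. Discs are
rasterised with an explicit inclusive rule (dist² ≤ r²) and the label
raster is exact, so the reported true class-2 percentage is exact. Isolated
discs keep a 3 px clear band from every other structure; if the requested
density cannot be placed within a bounded number of retries the generator
raises rather than silently degrading.

Annotation emulation draws, per class, small pure ellipses by rejection
sampling on the label raster. Half of the background ellipses are centred
within 3 px of a stained structure, mirroring standard
trainable-segmentation practice: annotators outline background tight
against objects so the classifier learns the bright/dark boundary. Without
those near-boundary examples the halo ring around each disc receives
inflated class-2 posteriors and the recovered percent area overshoots
ground truth by up to 2 percentage points at 9% density; with them the
pipeline recovers the true density to within ±0.6 points across densities
of 2–9%.

Deliberately not modelled: optical blur and chromatic aberration (structure
edges are hard), uneven illumination, staining gradients, tissue texture
inside fibers, touching vessels, and scanner-specific resolution
differences. Passing tests therefore demonstrate that the pipeline's
machinery — feature computation, training, probability calibration at the
45/255 filter, area arithmetic and the decision rule — is correct on images
whose class geometry is known exactly; they do not certify accuracy on real
stained tissue, which requires expert-annotated material.

## Numerical and design choices

- Grayscale conversion uses ITU-R BT.601 luma weights
  (0.299, 0.587, 0.114), rounded and clamped; 16-bit input is reduced by
  integer division of the full range (v → v >> 8) because every threshold
  in the pipeline lives on the [0, 255] scale.
- Ellipse membership is strict (< 1), so degenerate, sub-pixel ellipses
  select nothing instead of an ambiguous single pixel; pixel order is
  row-major for reproducibility.
- Degenerate metric denominators return 0 by convention (with a log note)
  rather than raising, keeping learning curves defined at their endpoints.
- The ROC sweeps distinct score values descending, anchors at (0,0)/(1,1),
  and integrates by trapezoid; tied scores move together, which makes the
  AUC equal the pairwise concordance probability with ties counted ½.
- Window variance is computed as E[x²] − E[x]² with a clamp at 0 to guard
  floating-point cancellation on constant patches.
- Determinism: every stochastic step (generator, annotation sampling,
  forest training) is driven by an explicit seed; identical inputs and
  seeds reproduce models, maps and reports byte for byte (`n_jobs=1`;
  no thread-dependent reductions).
- "Epochs": the ensemble's cumulative tree count is the iteration axis of
  the learning curve. No claim is made that any particular epoch count
  from other implementations transfers to this one.
- Problem sizes in the test suite: the density-recovery checks train on
  twelve 256×256 images per seed and evaluate at true densities of roughly
  2, 5 and 9% over five seeds; the packaged default canvas remains 512×512,
  which `scripts/acceptance.py` uses. The 256×256 choice keeps the full
  suite fast while leaving every structure size (discs 2–4 px, blobs ~12 px,
  largest feature window 17 px) unchanged.

## Known limitations

- The classifier is intensity- and scale-based; stains or tissues whose
  vessels are not darker than their surroundings need the polarity flag or
  retraining, and structures at scales outside σ ∈ [1, 8] px need a
  different scale list.
- Percent area is a pixel statistic, not a vessel count: it does not
  report capillary-per-fiber ratios or vessel morphometry.
- The 4% alert level is a clinical operating point taken as a default; it
  should be recalibrated for other stains, magnifications or scanners.
- Whole-slide pyramid formats are out of scope; inputs are single-frame
  TIFF/PNG photomicrographs.
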