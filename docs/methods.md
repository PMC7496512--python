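# Methods

This note documents the models behind `agglomsizer`, the defaults and
why they were chosen, what the synthetic scenes do and do not emulate,
and the numerical conventions used throughout. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The synthetic scene model

Real validation data for this kind of workflow are dark-field STEM
images of dispersed nanoparticles; none ship with the package, so the
generator in `agglomsizer.synth` is a first-class, tested component
that renders seeded scenes with exact ground truth. A scene is built in
this order:

1. **Agglomerates.** Each object is a union of 1–6 overlapping disks; a
   single disk is the single-particle case, which is counted as a
   minimal agglomerate just as single particles are folded into the
   agglomerate class in practice. The nominal diameter follows a
   lognormal law (default median 400 nm, shape σ = 0.35 — a moderately
   polydisperse dispersion of sub-micron agglomerates of ~100 nm
   primaries); satellites (0.35–0.75 of the primary radius) attach to
   the primary disk so the cluster footprint stays bounded at roughly
   2.2 primary radii and dense scenes remain placeable.
2. **Placement.** Rejection sampling, overlap forbidden. The exclusion
   margin is `2·(halo_width + ceil(2·psf_sigma)) + 4` px: objects must
   stay separated by more than the halo and blur footprint they each
   carry, otherwise their artifacts merge and per-object ground truth
   becomes ambiguous (which is the reason overlap is forbidden rather
   than merged). Exceeding 10 000 placement attempts raises an error
   naming the density problem; the stock defaults (18 objects in
   512 × 512 px at 15 nm/px) place successfully across hundreds of
   seeds.
3. **Halos.** Each object is wrapped in an annulus of width 2 px at
   `background + 0.3·(agglomerate − background)` gray levels — the
   phenomenological stand-in for small focus variations that brighten
   the rim of particles at low magnification. The defaults are a
   calibration of the artifact mechanism, not a measurement: they are
   set so that un-eroded segmentation measurably overestimates object
   size and the 1-px erosion step has something real to correct.
4. **Salt precipitates.** Star-convex polygons (5–9 vertices, 250–700
   nm) at mean gray level 17 000 — deliberately close to the
   agglomerate level of 20 000 so the intensity histograms overlap —
   carrying per-pixel multiplicative speckle (σ = 0.25). Texture, not
   brightness, is what separates salt from agglomerate; this is the
   property that makes best-case global thresholding fail by design.
5. **Probe blur.** The clean render is smoothed with a Gaussian PSF
   (default σ = 1 px). Real STEM edges have finite width; without it
   every edge would be 1 px sharp and the halo-inclusion artifact the
   erosion step exists to correct could not arise.
6. **Illumination.** A random degree-2 polynomial field scaled to a
   maximum relative deviation of 0.2 multiplies the image — gain-like
   shading, the model the correction stage assumes.
7. **Noise.** Additive Gaussian, σ = 300 gray levels on a background of
   1000 (detector noise of a few percent of the bright-object signal).
   A Poisson option is deliberately absent: nothing here characterizes
   a specific detector.

Ground truth (class map, per-object label map, halo mask, object table
with true Feret and area) reflects the clean pre-blur geometry. True
Feret diameters are computed from the rasterized object with the same
corner convention as the measurement path, so truth-vs-measurement
comparisons carry no rasterization offset.

The generator uses independent child RNG streams (placement, texture,
illumination, noise) spawned from one seed, so ablations — e.g. the
same shading field with and without objects — are exactly comparable.

**What the scenes do not emulate:** electron-optical physics (defocus,
astigmatism, scan distortion), structured support-film background,
touching or overlapping agglomerates, partial-volume edge intensities
beyond the Gaussian blur, and detector-specific noise. Passing tests
therefore show that the analysis recovers truth under controlled
artifact models of halo, salt, shading and noise — not that it is
validated on real micrographs.

## Scribble synthesis

Training labels are sampled from the interior (1-px eroded) pixels of
each true material class: agglomerate interiors get the *agglomerate*
label; plain background **and salt interiors** get the *background*
label (the two-class scheme of the workflow — correctly assigning salts
to the background class is the point of the classifier). Sampling takes
a fraction (default 0.02) of each pool, with a floor of 150 and a cap
of 3000 labels per pool. The floor matters: the interactive workflow
this emulates iterates "add labels until identification is consistently
accurate", and with pure proportional sampling the small salt regions
receive too few labels for the forest to learn their texture, letting
bright speckle patches leak through as false objects.

Halo-annulus pixels, and a 3-px guard skirt around each annulus, are
never sampled: both are brightened by the focal artifact and are
ambiguous by construction — a human annotator cannot say whether they
belong to the particle or the background, and labelling them background
teaches the forest to pull object boundaries inward, defeating the
halo-erosion correction downstream.

## Illumination correction

Dark-field shading is gain-like, so the model is multiplicative:
estimate a smooth strictly-positive field, divide, and rescale to
preserve the median background level. The default estimator masks
bright pixels (above the 75th percentile — objects must not inflate the
field) and fits a degree-2 polynomial surface by least squares. A
polynomial fit is exact for linear ramps and low-order vignettes and,
unlike kernel smoothing, is unbiased at image borders where one-sided
windows would otherwise tilt the estimate by several percent. A
large-kernel Gaussian estimator (normalized convolution, scale default
image width / 8) is available as `method="gaussian"`, and subtraction
could be composed manually where an additive model is preferred.
Correction is idempotent to tolerance and never changes object pixel
*support*, only intensities.

## Pixel classification

The feature bank is the conventional interactive-pixel-classification
family at scales σ ∈ {0.7, 1.0, 1.6, 3.5, 5.0, 10.0} px: Gaussian-
smoothed intensity, gradient magnitude, Laplacian, structure-tensor
eigenvalues (gradient products re-smoothed at σ), Hessian eigenvalues,
and local variance — 8 features × 6 scales. Derivative filters are
applied to the mean-subtracted image so that on a constant image every
derivative-type feature is exactly zero (truncated derivative kernels
do not otherwise sum to zero).

The classifier is a random forest: 100 trees, unlimited depth,
per-class balanced sample weights, fixed seed. The two class
probabilities sum to one per pixel by construction; the agglomerate
probability map is thresholded downstream at 0.5, the symmetric
two-class decision. Models serialize to a versioned joblib file so
training and batch prediction can run as separate steps.

## Measurement

* **Segmentation:** components of {p ≥ 0.5} under 8-connectivity
  (agglomerates are contiguous bright regions; diagonal splits would
  fragment them), minimum object size 4 px (a 2 × 2 object).
* **Halo correction:** every object is independently eroded once with a
  3 × 3 structuring element. Objects emptied by erosion are dropped and
  logged, not restored — restoring would reintroduce the bias the step
  removes. Erosion is monotone: area and Feret never increase with
  iterations.
* **Feret diameter:** maximum caliper distance over the convex hull of
  the unit-square *corner* points of the object's pixels (antipodal
  pair scan over hull vertices; exactly equal to the brute-force
  maximum over all corner pairs). The corner convention means object
  extent includes pixel extent: a single pixel has Feret √2. Row/col
  indexing, 0-based, origin top-left, everywhere.
* **Perimeter:** the 4-neighborhood boundary-walk estimator, falling
  back to the exposed-edge count for degenerate 1-px-wide objects where
  the walk estimator collapses to zero. With this estimator the form
  factor 4πA/P² of a rasterized disk of radius 20 px is 0.95 and of a
  large square approaches π/4 from above.
* **Axes:** the ellipse with the same second central moments as the
  pixel region, with a +1/12 per-pixel (unit-square) moment correction
  so a single pixel has nonzero axes. This is the standard
  moment-ellipse convention; note that for strongly elongated objects
  the ellipse major axis (4σ) can slightly exceed the Feret diameter
  (for a uniform rod, by a factor 2/√3 ≈ 1.15) — the two measure
  different things. Equivalent diameter √(4A/π) never exceeds the Feret
  diameter (isodiametric inequality).

## Statistics

For diameters *d*: number summary (arithmetic mean, SEM = sd/√n,
median, IQR); volume-averaged diameter (mean *d*³)^(1/3) — the diameter
of the sphere holding the mean per-object volume, the spherical-volume
constant cancelling; and the intensity-weighted mean Σ*d*⁷/Σ*d*⁶
simulating Rayleigh-regime (∝ *d*⁶) light scattering on known sizes.
Moment-ratio and power-mean inequalities guarantee
number ≤ volume ≤ intensity for every sample, with equality iff
monodisperse. The alternative volume-weighted mean Σ*d*⁴/Σ*d*³ is
available behind `method="weighted"` but is not the default reading of
"diameter of the mean volume". Treating agglomerates as spheres of
diameter = Feret overestimates the volume of elongated objects; this is
a stated limitation inherited from the construction itself.

The comparison test is Welch's unequal-variance two-sample unpaired
t-test with Welch–Satterthwaite degrees of freedom — the safer default
for "two-sample unpaired", reducing to Student's test under equal
variances. Two identical zero-variance samples return t = 0, p = 1 by
convention. No multiple-testing correction is applied: the workflow
performs single comparisons.

Histograms use half-open bins [lo, hi) of fixed width anchored at a
multiple of the bin width; counts (or weights) are conserved exactly
and an edge value falls in the upper bin.

## Validation

Objects are matched greedily in descending IoU order with (ref id,
test id) tie-break and a minimum IoU of 0.2 — deterministic and
symmetric in the matched-IoU distribution. Agreement is reported as
mean ± sd of matched per-object Jaccard indices (the headline figure)
together with the whole-field pixel Jaccard, the object-count ratio and
unmatched counts. The threshold baseline sweeps 256 global thresholds
and keeps the one maximizing pixel F1 against ground truth — an oracle
upper bound on what plain thresholding could achieve, which the trained
classifier must beat on salt-bearing scenes at the object-precision
level.

## Pipeline and reproducibility

The seven stages (synth → correct → train → predict → measure → stats →
validate) run from one config with one master seed; per-stage,
per-item seeds are derived through `numpy.random.SeedSequence`, so
stage-level reruns are stable and identical configs produce
byte-identical measurement CSVs. Training uses a random ~10% of images
(at least one), mirroring the train-on-a-subset protocol; the choice of
training images is random and unvalidated against other strategies. A
run manifest records stages, parameters, seeds and timings; a stage
failure writes a FAILED marker and keeps partial outputs.

## Problem sizes

The test suite and acceptance script use 512 × 512 px stock scenes
(15 nm/px, 18 agglomerates) in batches of 4–6 images, pooled over three
independently trained runs for bias estimates, and 384 × 384 px
salt-bearing scenes (10 agglomerates, 6 salt precipitates) over 10
seeds for the classifier-vs-threshold comparison — a few hundred
measured objects per quantity, chosen as the scale at which the
reported properties stabilize while a full run stays around a minute on
one CPU.

## Known limitations

* Halo width, salt morphology and blur are calibration choices of the
  phenomenological scene model, not measured instrument properties.
* Touching agglomerates are not split (no watershed); the workflow
  measures agglomerates as wholes, and the generator keeps objects
  resolvable by construction.
* Max-Feret is implemented; if a mean-Feret convention is required the
  per-object pixel sets are exposed for custom calipers.
* The moment-ellipse axes convention can exceed Feret for rod-like
  objects (above).
* Salt-bearing training scenes bias boundaries slightly inward (bright
  salt labelled background makes the forest conservative near bright
  rims); sizing accuracy is therefore validated on salt-free scenes,
  salt scenes on object precision.
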