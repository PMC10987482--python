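# Methods

`refplane` benchmarks the Z axis of a brightfield microscope with
polystyrene control beads: it defines a **reference effective focal plane
(REFP)** — the stage position at which the beads are most in focus — and
trains a convolutional ensemble to predict, from a *single* image, the
signed distance ΔZ (µm) between that image's focal plane and the REFP.
The nominal Z readout of a stage is not comparable across experiments or
instruments; the REFP provides the common origin that makes focal planes
reproducible.

## Synthetic bead model

Because every downstream stage must be testable without instrument data,
the package ships a generative optical model (`synth.OpticalModel`).  A
bead is a radial template, expressed as a fraction of the local
background intensity:

* a dark annular **rim** at the bead radius (9.5 px at 1.5 µm/px, i.e. a
  19 px diameter), depth 0.6, with a steep inner flank (σ = 3 px) and a
  gradual outer recovery (σ = 5 px) — the permanent pigmented body of the
  bead;
* a bright **center spot** (Gaussian, σ = 2.8 px) whose amplitude decays
  from 0.9 at focus following a Lorentzian in ΔZ.

The template is convolved with an anti-aliased disk kernel of radius
`rate · |ΔZ|` (defocus blur), background scales linearly with exposure
(120 counts at 12 ms) until the sensor clips at 255, and i.i.d. Gaussian
read noise (σ = 2 counts) is added before rounding to uint8.

Two asymmetries make the *sign* of ΔZ identifiable from one image, as it
is on real instruments where beads look visibly different above and below
focus: blur grows faster above focus (0.09 px/µm vs 0.05 px/µm below),
and the center brightness decays faster below focus (Lorentzian scale
24 µm below vs 45 µm above).  Both asymmetries vanish quadratically at
ΔZ = 0, so the model's invariants hold exactly: center intensity is
strictly maximal, and the radial profile's steepest slope most negative,
at the true focal plane.

The rim, rather than a uniformly dark body, is what keeps the
steepest-slope feature's sign stable: the center-to-rim falloff stays the
dominant (negative) slope across the full ±60 µm study range, whereas a
model whose only dark structure fades with defocus produces a
discontinuous sign flip in the feature-vs-Z curve.

What the generator does **not** emulate: cells and cell debris (beyond
elongated dark distractors for the detection filters), spatially varying
illumination, bead-size polydispersity, camera fixed-pattern noise, and
physical diffraction (the blur kernel is geometric).  Passing tests
therefore demonstrate the pipeline's correctness and its robustness to
the modeled effects — not instrument-grade performance on real images.

## Bead detection

Candidates are 8-connected clusters of the darkest 1 % of pixels.
Segmentation runs on a σ = 1 px Gaussian-smoothed copy of the image (the
percentile boundary otherwise lands in the flat rim trough, where sensor
noise makes mask outlines ragged enough to fail the shape filter); all
intensity measurements use raw pixels.  Each cluster is regularized
(hole filling — the bright bead center punches a hole in the dark mask
near focus — then morphological closing and opening with a 2 px disk) and
must pass, in order: area ≥ 180 px, circularity (4π·area)/perimeter² ≥
0.9, and std/mean > 0.1 on a sub-image padded by one bead diameter.

The perimeter estimator matters: naive boundary-pixel counting and
Crofton-type estimators both leave digitized squares at circularity
≈ 0.87–0.91, defeating the 0.9 threshold.  We measure the length of the
simplified marching-squares contour (Ramer–Douglas–Peucker tolerance
0.5 px), which keeps digitized disks of radius ≥ 8 px above 0.9 and
squares near their true π/4 ≈ 0.8.  A calibration test pins this
property.

## Radial profiles and the SS/CI features

Each accepted bead is cropped to a 64 px tile and its continuous center
found by minimizing the sum of squared residuals of a cubic smoothing
spline fit to pixel intensity vs. distance from the candidate center
(Nelder–Mead over (x, y), bounded ±8 px, one scatter point per pixel,
never binned).  The spline is implemented as a penalized cubic B-spline
(P-spline: uniform knots every 1.25 px, second-difference coefficient
penalty) — numerically equivalent to a smoothing spline on these
profiles at a fraction of the cost, which matters because the center
search evaluates the fit ~100 times per bead.  The smoothing parameter is
selected once per dataset by split-half cross-validation on the first
detected bead and then held fixed, so feature values are comparable
within a run; it is configurable.

From the full-radius fit (45 px):

* **background** = mean of the spline over 20–40 px from the center
  (shrunk to the maximum available distance and flagged in degenerate
  crops);
* **SS** = the spline-derivative value farthest from zero over 3–15 px,
  divided by background (signed; most negative at focus);
* **CI** = the spline value at 1 px from the center divided by background
  (maximal at focus).

Both features are scale-free: multiplying all intensities by a constant
(exposure change without clipping) moves them by < 1 %.

## REFP estimation

Per (experiment, exposure, FOV) and Z: per-bead IQR outlier removal
(k = 1.5, two-sided fences, linear-interpolation quartiles; with < 4
values everything is kept) and the median feature value; the median bead
image(s) — both middle beads when the count is even — set a saturation
flag for that point.  A GCV smoothing spline through each median curve is
aligned (additive shift in Z, multiplicative scale in feature value) to a
reference curve — the one with the most unsaturated points, ties to the
lowest exposure — by grid search over the shift at z_increment/4 with the
closed-form optimal scale per shift, then bounded local refinement.  A
pooled profile is a GCV spline over the union of aligned points; it is
refit per feature and per dataset.  Saturated points are excluded from
every fit and alignment, point-wise, not curve-wise, so a sweep that
clips near focus at high exposure still gets a REFP from its clean
flanks plus the pooled shape.

The pooled profile is then fit back to each curve and the feature REFPs
read off its extremum (SS minimum, CI maximum) on a z_increment/100 grid;
an extremum within half an increment of the sweep edge raises a boundary
warning.  Finally REFP = (REFP_SS + REFP_CI)/2, and the sweep-level REFP
is the median over curves.

## ΔZ regression

Tiles labeled ΔZ = z − REFP (positive above) train a convolutional
regressor after per-acquisition IQR removal on SS.  The engine is a
from-scratch numpy implementation (`nnet.py`): 3×3 convolutions as nine
shifted channel-matmuls, batch normalization, ReLU, 2×2 max pooling,
optional identity residual blocks, global average pooling, linear head;
Adam with classic L2; every backward pass is checked against float64
numerical gradients in the test suite.  Batch normalization is essential:
without it the network provably fails to train at the method's learning
rates.

Defaults follow the method's selected hyperparameters: initial learning
rate 1e-4 dropped by 0.9 every 15 epochs, batch 32, weight decay 5e-4,
20 % validation split, validation every 2000 steps (at least once per
epoch on small datasets, so early stopping stays active), patience 10
validations, 10 models, no input normalization (z-score, zero-center,
and average-background modes are available).  Patience is accounted in
optimizer steps (10 × 2000 = 20 000 steps at the defaults) so that its
meaning survives the change in validation cadence on small datasets;
gradients are clipped to global norm 5, a safeguard of this engine
against the loss spikes small-batch batch-norm training produces.  Augmentation is strictly
sharpness-preserving: translation ±5 px, rotation ±5°, reflections,
scaling 0.95–1.05, ±5 % multiplicative intensity jitter, bilinear with
reflective padding, applied on the fly at network resolution.  Targets
are internally divided by their standard deviation (predictions are
rescaled to µm), a pure conditioning choice that lets the same learning
rates work for any sweep range.

Inference is two-level: per model, IQR removal over the bead ΔZ
predictions and the mean of the survivors; ΔZ_final is the mean of the
per-model means.  Predictions outside the ensemble's training label
range are flagged as extrapolations.

## The scaled-down study (`study.py`)

Desk-scale conditions, fixed in `study.py` and used identically by the
acceptance script and the end-to-end tests:

* training sweep ΔZ ∈ [−60, +60] µm in 7.5 µm steps, exposures
  6/9/12 ms, 5 FOV × 8 beads (~2000 tiles), REFP estimated by the
  pipeline itself;
* reduced regressor: 32 px inputs (64 px tiles mean-pooled), three conv
  stages of 16/32/64 channels (depth-reduced but wide enough to clear
  the capacity plateau a narrower net exhibits), ensemble of 3;
* the initial learning rate is chosen by a short validation-RMSE probe
  over {1e-4, 3e-4, 1e-3, 3e-3} — the same selection criterion the
  full-scale hyperparameter optimization applies.  The optimal rate is
  scale-dependent: at ~5000 optimizer steps the probe selects a larger
  rate than the 1e-4 that wins at full scale with orders of magnitude
  more steps;
* held-out sweep from the same optical model with a different reference
  plane and bead layout, covering the inner half of the calibrated range
  (ΔZ ∈ [−37.5, +37.5], 11 levels × 3 exposures × 2 FOV = 66
  acquisitions — real test sweeps are likewise acquired well inside the
  training range), 6 beads per acquisition after SS filtering.  The
  single-model comparisons use the ensemble member with the lowest
  validation RMSE — the member a practitioner would deploy on its own.

Problem sizes (bead counts, Z levels, epochs) were chosen so the whole
study runs in minutes on one CPU core; the methods scale to instrument
data unchanged.

## Numerical choices and degenerate inputs

* Quartiles: numpy's linear interpolation; the IQR example
  [1,2,3,4,100] → fences [−1, 7] depends on it.
* Constant images: percentile threshold marks everything; the area and
  circularity filters reject the single giant cluster.
* Z-score normalization of a constant tile raises an error (σ = 0).
* Alignment requires ≥ 4 unsaturated points and at least half of the
  fixed curve inside the shifted domain of the moving spline, so
  residuals at different shifts are comparable.
* Center optimization falls back to the best evaluated point (flagged)
  if the simplex fails; ties in max pooling give the gradient to the
  first maximum.
* All randomness flows from integer seeds through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  images and models.

## Known limitations

* The optical model is geometric, not diffractive; absolute SS/CI values
  are not comparable to any real instrument's.
* Feature precision is quantization-limited at the dimmest exposures: at
  a 60-count background the radial slope is ~8 counts/px and uint8
  rounding alone moves SS by about a percent, so sub-percent feature
  comparisons are only meaningful above that floor.
* The sign asymmetries are plausible but not fitted to any instrument;
  on a system with nearly symmetric defocus the single-image sign
  recovery would degrade gracefully into |ΔZ| estimation.
* The reduced network is exposure-sensitive at its lowest exposure
  (6 ms); the full-depth configuration and larger datasets close that
  gap at full scale.
* Pooled profiles are per-dataset; transferring one across instruments
  without re-fitting is out of scope.
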