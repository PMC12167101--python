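# Methods

`nsa-vision` measures the radiographic neck-shaft angle (NSA) of a hip
resurfacing prosthesis from paired anterior-posterior (AP) and lateral
views, and corrects the AP value with a small neural network trained
against clinician ground truth. This note documents the models,
parameters, numerical choices, and what the synthetic validation does
and does not demonstrate.

## Angle conventions

All axis angles are signed degrees from the image horizontal,
counter-clockwise positive with y up, folded into `(-90, 90]` (a
vertical axis is `+90`, never `-90`). Under this shared reference the
femoral shaft is near-vertical with a positive angle (`a_f ≈ +75…+90`)
and the prosthesis stem oblique with a negative one
(`a_p ≈ -85…-35`), so the NSA is

```
NSA = |a_f| + |a_p|
```

which equals the geometric angle between the distally-directed shaft
axis and the proximally-directed stem axis precisely because the two
signed angles have opposite signs. The synthetic generator enforces
that sign convention; for configurations where both structures tilt
the same way the sum-of-absolutes formula and the inter-axis angle
diverge, which is why `SceneParams` rejects them.

## Clinician ground truth: the trapezoid technique

The reference NSA treats each elongated structure as a quadrangle: two
transverse segments are marked across it and the axis is the line
through their midpoints. The angle between shaft and neck (or stem)
axes is the NSA. `ground_truth.axes_angle` returns the directed angle
between the axes as given; `nsa_from_landmarks` reduces each axis to
its folded signed angle and sums the absolute values, which makes the
result independent of how each axis happens to be oriented. On every
generated scene this construction recovers the generating NSA to
better than 1e-6 degrees (the module-pair consistency test).

## Synthetic scenes

Each scene is a 320×320 8-bit image: background 30, femoral shaft
band at intensity 180, prosthesis (hemispherical cup + stem) at 250,
plus additive Gaussian noise (default σ = 10). The implant is rendered
self-similar — stem length is 3.2× the cup radius — mirroring how
resurfacing implants scale with head size; this also means a template
scaled to match the cup matches the stem tip. Structure sizes (cup
radius 26–34 px, shaft width 22 px) are chosen so that edge segments
are tens of pixels long, as implant edges are on clinical radiographs;
at substantially smaller scales the pixel-staircase quantisation of
short digital edges alone contributes ~2° of angle error and the
measurement floor rises accordingly.

The lateral view reuses the AP geometry with the stem angle perturbed
by `Normal(0, σ_lat)` (default σ_lat = 3°), emulating projection
differences between views; the recorded AP ground truth comes from the
unperturbed geometry.

Cohorts draw per-hip NSAs from a normal distribution centred at 140°
(SD 6.77°, matching the dispersion reported for manually measured
resurfacing NSAs) truncated to [120, 160], the shaft angle uniformly
from [75°, 88°], and assign hips to patients with a ~9% unilateral /
91% bilateral mix (26 bilateral + 5 unilateral patients at n = 57).

What the phantom does **not** emulate: bone texture, cortical
tapering and bowing, soft tissue, beam geometry, exposure variation,
or neighbouring anatomy. Passing tests therefore demonstrate the
correctness and internal consistency of the measurement chain, not
its accuracy on clinical films.

## Measurement pipeline

1. **Preprocess.** Grayscale conversion (BT.601 weights) and a
   bilateral filter (neighbourhood 9×9, σ_color = 50 intensity units,
   σ_space = 5 px; reflect padding). The filter is a convex
   combination of neighbourhood pixels, so output intensities never
   leave the input range and high-contrast edges move by less than a
   pixel.
2. **Detect.** Exhaustive stride-1 mean-squared-error template
   matching of 5 rendered reference prostheses at scales
   {0.8, 1.0, 1.25}. The MSE surface is computed with an FFT
   cross-correlation plus integral-image window sums; candidates
   within a small absolute slack of the surface minimum are re-scored
   exactly, so the selected placement (row-major position, then lower
   template index, then smaller scale on ties) is identical to a
   brute-force scan. Each template records its own cup centre and stem
   tip, which matching maps into image coordinates. The femur search
   region is the rectangle directly below the prosthesis box (same
   x-extent, twice its height, clipped to the image); the pipeline
   additionally pads it laterally by 15% per side because the tight
   implant box can let the shaft graze its border.
3. **Angles.** Canny edges (σ = 1.2, hysteresis 50/150 on the 0–255
   scale) followed by the probabilistic Hough transform
   (θ resolution 1°, vote threshold 10, line gap 3, minimum segment
   length 20 px). The probabilistic variant returns finite segments,
   which makes "minimum length of detected lines" well defined; it
   samples edge pixels in random order, so every call takes an
   explicit seed and the pipeline derives per-hip per-view seeds from
   the run seed. Segment angles come from the endpoints, folded into
   `(-90, 90]`. Each region's angles are reduced by the median, and
   `NSA = |median femur angle| + |median prosthesis angle|`.

Three robustness measures shape the line search, all following from
the geometry of the detection box:

* the prosthesis box necessarily overlaps the proximal shaft (the stem
  tip sits on it), so prosthesis-ROI lines within 15° of the measured
  femur orientation are attributed to the shaft and dropped;
* the matched cup disc and the stem-tip junction are blanked out of
  the edge map (margin 3 px + 4×Canny σ): the cup boundary is a curve
  whose short chords otherwise pass for stem edges, and the smoothed
  corner at the stem-shaft junction curls the edge contour and tilts
  adjacent segments;
* the femur minimum segment length scales with the ROI height
  (0.45×height, clamped to [40, 75] px), because long segments bridge
  the pixel staircase of near-vertical edges that otherwise yields
  spurious exactly-vertical lines; a graduated fallback ladder
  (75→40→20 px) retries with shorter segments before a region is
  declared unmeasurable. A hip with no detectable lines in either
  region is recorded as a failure — the analogue of excluding
  inadequate imaging — never silently dropped.

With these defaults the end-to-end AP measurement error on default
cohorts is ≈0.55° MAE, below 2° worst-case on noiseless scenes, and
the prosthesis centre is localised within 5 px essentially always.

The two Hough knobs (`min_line_length`, `vote_threshold`) can be
re-tuned on a held-out fraction of a cohort with `tune_hough`, which
grid-searches them against known-geometry scenes and breaks ties
toward the larger (more conservative) values.

## Two-view fusion

A fully connected network (2 inputs → two hidden layers of 128 ReLU
units → 1 sigmoid output) maps the AP and lateral CV NSAs to a
corrected AP NSA. Features and target are min–max scaled to [0, 1]
over [90°, 180°]; the default loss is binary cross-entropy on the
scaled target — with a sigmoid output this is a proper scoring rule
minimised exactly at the target — and plain squared error is available
as an alternative. Optimisation is full-batch Adam (lr 3e-3, 400
epochs; longer training measurably overfits cohorts of ~45 training
hips, so the epoch count acts as the regulariser). Records are split
80:20 with the train side floored (57 hips → 45 train / 12 test), by
patient by default so bilateral hips never straddle the split.
Training is bit-reproducible given the config seed.

### The fusion study's error model

On the geometric phantom the vision pipeline is essentially
noise-immune (the bilateral filter and the median over segment angles
absorb even σ = 60 pixel noise), leaving an unbiased AP error of
~0.55°. In that regime the AP estimate is already the minimum-variance
estimator of its own film's NSA, and no function of (AP, lateral) can
improve on it — the lateral view differs from the AP truth by the
projection perturbation and so carries no usable extra signal.
Clinical radiographs are different: reported automated measurements
carry a systematic offset (cohort means 135° automated vs 138° manual)
and a pre-fusion MAE near 3.1°, arising from anatomy the phantom
deliberately omits (bowed, tapering cortices, clutter, exposure).

Fusion experiments therefore add a view-level error to each measured
NSA: `CvErrorModel` applies a −3° AP offset plus Gaussian noise with
σ = 2.2° per view, which reproduces that published pre-fusion
operating point (MAE ≈ 3.1°). Against cohorts so degraded, the network
recovers most of the offset and averages the two views' independent
noise: fused test MAE ≈ 1.5–2.0° versus ≈ 3.2° for the raw AP
estimate, with Spearman correlation rising accordingly — the same
direction and magnitude of improvement reported for the clinical
cohort (3.09 → 1.94). The error model's parameters are calibrated to
those published values, not fitted to any test outcome.

## Evaluation

Agreement between predicted and ground-truth NSAs is summarised by
Spearman's rank correlation (with its large-sample p-value), the
coefficient of determination against truth `R² = 1 − SSres/SStot`
(this form penalises bias, unlike the squared correlation of a refit
line), MAE, and MSE. A Kruskal–Wallis H test (tie-corrected, χ²
p-value) is exposed for group comparisons; identical values across all
groups return `H = 0, p = 1` by convention. Constant inputs make rank
correlation or R² undefined and are rejected or flagged as NaN rather
than silently reported.

Reliability follows the shuffled-repetition protocol: each repetition
reshuffles the patient order with seed `base_seed + r`, re-splits,
re-trains, and scores both the fused and the raw-AP arm on that
repetition's held-out fold; the summary stores every repetition's
metrics together with their means and standard deviations. The test
suite uses 50 repetitions (the protocol itself scales to 1000 by
argument).

## Degenerate inputs and tie-breaks

* Template matching ties: first placement in row-major order, then
  lower template index, then smaller scale.
* Median of an even number of angles: arithmetic mean of the middle
  two.
* `tune_hough` ties: larger minimum line length, then larger vote
  threshold.
* Records outside the [90°, 180°] scale range are excluded from
  training with a warning and reported in the split report.
* A constant truth vector flags R² as NaN; constant vectors are
  invalid for rank correlation.

## Problem sizes used in validation

Oracle consistency is checked on 100 scenes; detection equivalence on
20 exhaustive small instances plus 50 noisy scenes; angle accuracy on
50 noiseless and 50 noisy scenes; the fusion ordering on five measured
57-hip cohorts cycled over 20 replicates, each under the 50-repetition
reliability protocol. These sizes keep the full suite at desk scale
while leaving every stage exercised end-to-end.

## Known limitations

* The phantom's clean geometry understates real-film measurement
  error; the fusion study's error model reintroduces it statistically,
  not photometrically.
* Template matching is not rotation invariant; orientation coverage
  comes from the bank (five stem orientations spanning [−80°, −35°])
  plus the scale sweep.
* One prosthesis per film is assumed; bilateral hips must be provided
  as separate cropped images.
* The lateral ground-truth NSA is generated and recorded, but
  evaluation scores only AP predictions (no manual lateral reference
  exists to compare against).
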