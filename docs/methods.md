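# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of the momofuse pipeline.

## Problem setting

One recording session observes a person performing a sequence of
activities of daily living through three sensor families at different
rates: ambient binary channels (switches, PIR; ~10 Hz effective), inertial
channels (accelerometer/gyroscope, ~25 Hz, optionally with orientation
quaternions), and a static camera (~10–25 fps).  The task is to assign
each 4-s window one of K activity classes.  All streams carry per-sample
integer labels; windows take the majority label (ties break toward the
smaller class id, a fixed, order-independent rule).

## Per-modality preprocessing

**Ambient.** Zero-phase Butterworth low-pass (order 3, cutoff 5 Hz,
both configurable), applied forward–backward (`sosfiltfilt`).  ADL-band
information lives well below 5 Hz and switch traces are steps, so the
filter removes contact bounce without phase delay.  Forward–backward
application squares the magnitude response: the amplitude ratio at the
cutoff is 1/2, not 1/√2 — a property the tests pin down.

**Inertial.** Per-channel wavelet shrinkage: db4, 3 decomposition levels,
universal threshold `σ√(2 ln n)` with σ from the finest-level median
absolute deviation, soft rule by default.  A *noise-floor gate* skips
shrinkage entirely when the universal threshold falls below 10% of the
signal RMS: in that regime the detail coefficients are dominated by
genuine signal leakage (a clean low-frequency tone has real energy in the
detail bands) and soft shrinkage would only bias it.  The gate is what
makes the filter idempotent and transparent on clean signals while still
removing σ≈0.5 noise (tests verify both directions).  Orientation
quaternions are renormalised to unit length; a row with norm < 1e-8 is a
degenerate orientation and raises.

**Vision.** The static background is the per-pixel median over the
session's frames (long sessions are subsampled to ≤200 evenly spaced
frames, which leaves a median essentially unchanged while bounding
memory).  Foreground = |frame − background| > 25 (8-bit), cleaned by
morphological opening then closing with a radius-2 disk.  This assumes a
static camera and a subject that occupies any given pixel a minority of
the time.

## Skeleton model

Twelve named points: head, shoulders, elbows, wrists, torso, knees,
ankles.  (Some descriptions of such models count eleven points with a
neck; the evaluation tables this package mirrors list twelve with
shoulders and no neck, so twelve is the implemented set.)

Extraction is deterministic geometry on the largest connected silhouette
component (≥200 px, configurable):

1. torso = distance-transform maximum (thickest body part);
2. head = local distance-transform maximum of the top band (top sixth of
   the bounding box) — the head-disk centre, more stable than the topmost
   medial-axis pixel, which sits on the rim;
3. shoulders = lateral extrema of the thinned skeleton in a row band one
   fifth of body height below the head, with the lateral search capped at
   0.16 × body height so a near-horizontal arm cannot masquerade as a
   shoulder (anthropometric shoulder half-width is ≈0.11–0.13 height);
4. wrists/ankles = skeleton endpoints in the four quadrants around the
   torso (wrist = farthest endpoint from its shoulder, ankle = lowest
   endpoint on its side; endpoints within 0.12 × height of the head are
   excluded from wrist candidacy);
5. elbows/knees = chord midpoints between their proximal anchor and the
   detected extremity (hip anchors at torso + (±0.08 H, 0.12 H)).

Left/right follow image-x order (single fixed camera, no pose flipping).
Per-point confidence = distance-transform value at the point divided by
the component maximum — deterministic, in [0,1], high for deep interior
points and degrading exactly when the silhouette thins or erodes.

Evaluation uses the scaled Euclidean distance `D_j = √Σ(XₙSₙ − YₙSₙ)²`
with S = 1 by default (S is exposed for resolution normalisation) and
the recognition rule `D_j ≤ 15 px` at 640×480.  At other resolutions the
threshold scales with frame height (7.5 px at 320×240, the generator's
default).  Missing detections count as failures.

## Feature families

* **Pearson gate** (ambient): correlations of all unordered channel
  pairs; the feature vector is the upper-triangle correlations, the mean
  absolute correlation, and the 0.04-threshold flag.  Using *absolute*
  values makes the gate sign-agnostic: a switch that opens while another
  closes is still co-activity.  Constant channels (silent switches)
  correlate 0 by convention, so idle windows do not fire.  A
  single-channel stream falls back to lag-1 autocorrelation (logged).
* **LPCC** (inertial): per channel, order p = 10 LPC via Levinson–Durbin
  (statsmodels' implementation behind the package surface, cross-checked
  in tests against a direct Toeplitz normal-equations solve), then d = 12
  cepstral coefficients by the t/x-weighted recursion; at x = p both
  recursion branches coincide up to the aₓ term, and the convolution
  treats out-of-range a-indices as zero.  A flat or too-short channel
  contributes a zero block so the feature length stays fixed.
* **SLIF** (vision): three rings at (8, 16, 32) px with 16 spokes, all
  twelve skeleton points as anchors by default; each anchor contributes
  its ring/spoke occupancy samples (off-image = 0) plus one occupancy
  fraction; per-frame descriptors are mean-pooled within the window.

## Fusion and cross-entropy selection

Ambient and motion tables share the window index; vision frames are
assigned to the window whose [start, start+4 s) interval contains their
timestamp and mean-pooled.  A window lacking a modality gets that span
zero-filled and flagged.  Span metadata records each modality's index
range and survives masking.

CEM searches binary masks: population 50, elite fraction 0.2, 30
iterations, smoothing 0.7, initial inclusion probability 0.5, Bernoulli
parameters clamped to [0.01, 0.99] so no dimension is absorbed
prematurely.  Sampled all-zero masks are repaired by forcing one random
dimension on.  The **fisher scorer** is a penalised additive criterion:
per-dimension ratio `F_j = B_j / (W_j + 0.05 (B_j + W_j))` (between- and
within-class scatter; the 5% mixing bounds a zero-within dimension at 20
instead of letting it drown the rest), and mask score
`Σ_{j∈mask} (F_j − λ)` with rent `λ = 0.5 · mean_j F_j`.  A plain trace
ratio `ΣB/ΣW` was rejected during design: it is indifferent between one
informative dimension and ten equally informative ones, so it cannot
reward completeness, and the optimiser collapses onto a single dimension.
The additive form is also mask-separable, which lets CEM score a whole
population with one matrix product.  A `cv_loss` scorer (negative 3-fold
stratified nearest-centroid error) is available when a
classification-aligned fitness is preferred.  Degenerate landscapes
(identical scores three iterations running) stop early with the best
mask so far.

## Recursive neural network

Leaves: one affine + tanh map per modality span into ℝⁿ (n = 64), so
leaves live in the same (−1,1)ⁿ space as internal nodes.  Composition:
`parent = tanh(W [left; right])` with a single shared W ∈ ℝ^{n×2n}
applied at every internal node; the default tree is left-deep
((ambient∘motion)∘vision) with a balanced option — the simplest
order-stable cascades over three children.  Leaves use their own maps
rather than sharing W (their input dimensionalities differ; documented
design choice).  Head: affine + softmax.

Training: mini-batch gradient descent with momentum 0.9 (lr 0.01, 200
epochs, batch 32, L2 1e-4 on weights, all configurable) on hand-derived
backpropagation-through-structure gradients; a central-difference check
on every parameter block (rel. error ≤ 1e-4) guards the derivation.
Inputs are standardised internally and the constants stored with the
parameters, so persisted models reproduce their predictions exactly.
Initialisation is seeded Gaussian scaled by 1/√fan-in; the seed also
fixes batch order, making final losses bit-reproducible.

Evaluation: stratified k-fold (k = 10; reduced with a warning when the
smallest class has fewer windows), per-fold plain accuracy, pooled
predictions → row-normalised confusion matrix, and **macro accuracy** =
unweighted mean of the diagonal over supported rows.  Macro accuracy is
the headline statistic because it is the only definition under which the
bundled benchmark tables' printed summary values follow from their
matrices; the cross-dataset mean is the simple average of the two
per-dataset macro accuracies.

## Synthetic study conditions

Defaults: 9 classes (class 0 idle), 12-s segments, 4 segments per class
(432 s, 12 windows per class — the smallest size that supports stratified
10-fold with at least 10 windows per class), 4 ambient channels at 10 Hz,
6 inertial channels at 25 Hz, 320×240 frames at 10 Hz (scaled from
640×480 for speed, with the 15 px rule scaled to 7.5 px), inertial noise
σ = 0.1, ambient coupling 0.9.

Class-intrinsic parameters depend only on the class index (fixed PRNG
stream per class), so every session draws from the same activity
population; the session seed drives schedules, phases and noise.
Per class k ≥ 1: fundamental frequency 0.8 + 0.4k Hz with a weak second
harmonic and a class-specific per-channel amplitude pattern; switch
events from a random telegraph (toggle probability 0.04 + 0.01k per
sample) copied by a class-specific subset of channels with probability
= coupling, else an independent telegraph; stick-figure arm swing
4 + 0.75k degrees and lateral gait 3 + 0.8k px.  Class 0 is idle: no
oscillation, switches at rest (exactly zero — binary switches carry no
additive noise; their stochasticity is toggle timing), minimal body sway.
The figure drifts slowly across the frame so every pixel stays
background-majority and median background subtraction remains valid;
limbs are drawn near-straight so chord midpoints coincide with elbow and
knee ground truth, and the legs attach inside the torso ellipse so the
silhouette stays one connected component.

What the generator does **not** emulate: appearance variation, occlusion
and self-occlusion, camera noise and exposure changes, sensor drift and
dropout, label noise, within-class execution diversity, and transitions
blending two activities inside one window.  Passing the end-to-end tests
therefore shows the pipeline's machinery is correct and the stages
compose — not that the accuracy figures transfer to real recordings.

## Numerical choices and degenerate inputs

- Pearson correlation of a constant input returns 0 with a degeneracy
  flag; denominators guard at 1e-300.
- `lpcc` treats convolution terms with a-indices outside 1..p as zero;
  the brute-force oracle equivalence is tested to 1e-12 on 200 seeded
  inputs.
- `tanh` saturates to ±1.0 in float64 for |x| ≳ 19; "strictly inside
  (−1,1)" therefore holds for moderate weights and is asserted as a
  closed-interval bound for extreme ones.
- Windows shorter than the signal produce an empty list (logged), not an
  error; a signal shorter than 3(order+1) samples rejects the zero-phase
  Butterworth.
- Confusion rows with zero support are all-zero and flagged, and are
  excluded from macro accuracy.
- The bundled benchmark tables are transcribed as printed, including one
  row that sums to 1.10; the anomaly is reported, not corrected, and the
  summary accuracies are recomputed from the diagonals at run time.

## Known limitations

- The geometric skeleton extractor assumes a single upright person with
  raised or lowered-but-lateral arms; crossed limbs, sitting poses or
  multi-person scenes are out of scope.
- The Pearson gate needs ≥2 ambient channels for its intended semantics;
  the autocorrelation fallback is a pragmatic stand-in.
- CEM with the fisher scorer optimises a linear-separability proxy; for
  feature interactions only the (slower) cv_loss scorer is sensitive.
- Plain SGD with momentum is deliberate (deterministic,
  dependency-light); badly scaled custom features should be standardised
  — training does this internally, but persisted masks/models assume the
  same feature layout at inference.
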