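# Methods

## Problem and approach

Red blood cells (RBCs) flowing through microcapillaries of roughly their
own diameter adopt two stable morphologies: the axisymmetric **croissant**
at low flow velocities and the non-axisymmetric, off-centerline **slipper**
at higher velocities.  A large fraction of observed cells, however, are in
transition or otherwise indefinite ("**other**"), and any classifier that
forces every cell into one of the stable classes misrepresents exactly the
regime of interest — the phase transition.

`rbcshape` implements an *outlier-tolerant* classifier built around a small
**regression** CNN.  Instead of a softmax over classes, the network maps a
90 × 90 px 8-bit crop of a single cell to one scalar score on an
8-bit-inspired axis.  Training targets are −127 for slippers, +127 for
croissants, and +64 for an auxiliary class, the **sheared croissant**
(most plausibly a slipper rotated 90° about the flow axis), which is
included only to sharpen the croissant end of the axis.  After training,
the score spectrum of a whole recording is decomposed into four Gaussians
(three class populations plus a broad background); class decisions are
intervals on the score axis, and every score falling in neither interval
is "other".  Aggregated per flow condition, the decisions yield the shape
**phase diagram** whose slipper/croissant crossing is the phase-transition
point.

## Network

Architecture (`ModelSpec`): three stages of valid (no-padding, stride-1)
convolution → reLU → 2 × 2 stride-2 max pooling, then one fully connected
linear output node.  With 21 × 21, 14 × 14 and 6 × 6 kernels on 90 × 90
input the feature-map side lengths are 70 → 35 → 22 → 11 → 6 → 3; the head
connects all `n₃ · 3 · 3` remaining values to the scalar output.  The
first stage uses 25 kernels by default.  The kernel counts of stages 2 and
3 are free parameters (default 25, matching stage 1); the scaled-down
profile `ModelSpec.small(8)` keeps the kernel sizes and uses 8 maps per
stage, which is what the shipped pipeline and tests train (the full
25-map model is exercised for its architecture arithmetic only — it learns
the same task, just several times slower).

The input layer applies a fixed affine conditioning `(x − 127.5) / 127.5`,
mapping the 8-bit range to [−1, 1].  This mirrors the zero-centering that
mainstream deep-learning toolboxes apply silently at their image input
layers; without it the stated learning rate is unstable on raw 0–255
inputs (see *Training stability*).

Convolutions are evaluated in the Fourier domain (zero-padded real FFTs at
fast lengths), which is exact linear correlation up to roundoff and far
cheaper at these kernel sizes than direct sliding windows.  Forward and
backward passes are analytic; a finite-difference check (relative error
< 1e-4 on ≥ 20 randomly chosen parameters in float64) is part of the test
suite.  Weights are He-initialized (zero-mean normal, std `sqrt(2/fan_in)`),
biases zero, all seeded.  The working precision is float32 for training
speed; float64 is available for numerics tests.

## Preprocessing

1. **Contrast stretch**: intensities are mapped to the full 8-bit range so
   that the bottom and top 1 % of pixel values saturate
   (linear-interpolation quantiles; the convention changes results by at
   most one grey level).  Constant images have no contrast and are
   returned as mid-grey with a warning.
2. **Tukey window** (taper fraction α = 0.25): every row is weighted by

       w(y) = ½[1 + cos(2π/α (y − α/2))]        0 ≤ y < α/2
       w(y) = 1                                  α/2 ≤ y < 1 − α/2
       w(y) = ½[1 + cos(2π/α (y − 1 + α/2))]    1 − α/2 ≤ y ≤ 1

   with y = i/(n−1) the relative row position (endpoints included, so the
   extreme rows get weight 0).  Only the vertical (cross-channel) axis is
   tapered: the channel walls refract light irregularly, and the fade-out
   removes those bands.  The stretch runs first (on the 8-bit crop), the
   window second; the real-valued result feeds the network.
3. **Mirror augmentation** (training only): every crop is duplicated
   reflected across the horizontal centerline — the physics is symmetric
   under that reflection — doubling 4,000 labeled cells to 8,000.

## Training

Loss: RMSE between outputs and class targets, per mini-batch.  Optimizer:
classical-momentum SGD,

    v ← γ v − α ∇E(σ),   σ ← σ + v,

with constant learning rate α = 0.001, momentum γ = 0.9, mini-batches of
128 images from the seeded-shuffled training partition (final short batch
kept), at most 10 epochs.  5 % of the data is held out for validation;
the validation RMSE is evaluated every 50 mini-batches and five
consecutive strictly-rising values stop training early (overtraining
guard).  "Rising" compares each value to its immediate predecessor, not to
the best-so-far.

**Training stability.**  A plain implementation of this protocol is
fragile: depending on the initialization seed, momentum-amplified gradient
spikes can drive every rectifier unit negative within a few dozen
iterations, after which the network is dead and outputs a constant.  Two
safeguards make all tested seeds converge:

* the fixed input conditioning above (raw 0–255 inputs collapse even for
  benign seeds), and
* direction-preserving global gradient clipping
  (`TrainingConfig.grad_clip_norm`, default 20; `inf` disables it): the
  gradient is rescaled whenever its global L2 norm exceeds the threshold,
  before the momentum update.  The threshold sits well above the typical
  early-training norms (~20) and bites only on the transient spikes
  (norms in the hundreds) observed at the convergence plateau.

`sgdm_step` itself implements the unmodified momentum recursion; clipping
happens in the training loop.

## Score calibration

The score histogram (default bin width 5 units on the ≈ [−150, 150] axis)
is fitted by the sum of four Gaussians via nonlinear least squares
(`scipy.optimize.curve_fit`).  Initialization: the three largest local
maxima of the lightly smoothed histogram seed the class centers; the
background starts wide (σ = half the score range) at the spectrum mean.
After fitting, the widest component is labeled background and the rest are
assigned slipper / sheared croissant / croissant by center order.  The fit
requires ≥ 12 occupied bins and reports its RMS residual.

Two threshold rules:

* **k·σ**: intervals `μ ± k·σ` around the fitted slipper and croissant
  centers (the sheared croissant never gets an interval — it is auxiliary).
* **Adapted**: per class independently, scan candidate (center,
  half-width) pairs and keep the pair minimizing
  false positives + false negatives against reference labels (sheared
  croissants count as non-members of both intervals).  Ties prefer the
  narrower interval, then the lower center.  The default grid spans ±1
  fitted σ around each center (step 0.5) and 0.5–4 σ in half-width
  (step 0.5).  The implementation is vectorized but exactly equivalent to
  exhaustive enumeration, and is tested against an independent brute-force
  oracle.

## Classification and reporting

A score is a slipper (croissant) when it lies inside that class's interval,
boundaries inclusive; if overlapping intervals both contain it, the nearer
center *in half-width units* wins; otherwise the cell is "other".  Phase
diagrams report per-condition fractions of the three decisions, with the
condition axis taken from per-cell velocity when available and the applied
pressure drop otherwise (the pressure→velocity map is an experimental
calibration outside this package's scope).  The transition point is the
first zero crossing of the piecewise-linear interpolation of
slipper − croissant fraction.  Confusion matrices cross-tabulate reference
labels (rows) against predictions (columns) with row percentages, plus
false-positive / false-negative id lists per class.

## Synthetic data

No suitable public corpus of such recordings exists, so the package ships
a parametric generator that renders labeled 90 × 90 crops:

* **croissant** — difference of two offset ellipses (a crescent opening
  against the flow), exactly mirror-symmetric about the horizontal
  centerline;
* **slipper** — sheared elongated ellipse displaced 8–12 px off the
  centerline with a trailing tail lobe;
* **sheared croissant** — croissant with deliberately broken top–bottom
  symmetry;
* **other** — random morphs between the class templates with added
  angular-lobe warping.

Photometric chain, in order: illumination scaling (uniform in 50–80 % of
full lamp power per image, as in the recordings), Gaussian defocus blur
(σ = 1.2 px), additive Gaussian sensor noise (σ = 4 grey levels),
integer-pixel translation jitter (±3 px), darkened cosine-ramp bands over
the top/bottom 8 rows (emulating channel-wall refraction, and giving the
Tukey window something to remove), then clipping and 8-bit quantization.
Per-class geometry parameters are drawn fresh per image from narrow ranges
so each class has natural within-class spread.  Pixel scale is treated in
px directly (cell bodies span roughly 55–65 px, consistent with "typical
cell dimensions ≈ 80 px" in a 90-px crop); no µm calibration exists or is
needed.

The training mix defaults follow the study design (equal slippers and
croissants, fewer sheared croissants; class-typical pressure drops
700–1000 / 100–200 / 300–500 mbar).  The evaluation generator
`generate_phase_sweep` plants a known phase transition: at each of the 12
pressure drops (20–1000 mbar) the slipper share of the stable cells follows
a logistic curve crossing 1/2 at the planted transition (default
400 mbar), a constant 15 % of cells are "other", and sheared croissants
peak (20 %) around the transition.  Because slipper and croissant split
the stable share complementarily, their fraction curves cross exactly at
the planted value.

**What the generator does not emulate**: real optical texture (biconcave
interior contrast, diffraction rings), cell-to-cell biological
variability beyond the parametric ranges, asymmetric defocus, motion blur,
cell rotation dynamics, or hydrodynamic interactions.  Passing tests
therefore demonstrate that the pipeline's machinery — preprocessing,
optimization, calibration, thresholding, reporting — is correct and that
the network can learn the class-defining gross geometry; they do not
certify accuracy on experimental recordings, whose error rates (slipper
false-detection rates of several percent are typical for this approach on
real data) depend on image statistics this generator idealizes.  The
near-perfect synthetic confusion matrices should be read in that light.

## Scale of the shipped runs

The default pipeline (`PipelineConfig`) renders 2,000 training cells
(750 / 750 / 500), mirrors them to 4,000, trains the 8-map model for the
full protocol, and evaluates on a 720-cell sweep (60 per pressure).  This
runs in a few minutes on one CPU core and reaches a final training RMSE
around 7–10 on the 254-unit target scale, with fitted population centers
within a few units of the training targets.  All sizes, counts and seeds are config fields;
nothing in the library assumes the desk-scale values.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation; contrast stretch of a constant image →
  mid-grey 128 with a `RuntimeWarning`.
* Histogram binning covers [min, max] with the last edge closed; counts
  are conserved.
* Mixture fit: bounded parameters (σ > 0, amplitude > 0);
  non-convergence raises with the initialization embedded in the message.
* Interval boundaries are inclusive; the slipper wins exact half-width
  ties (deterministic, arbitrary).
* Transition: first crossing reported; a condition whose fractions touch
  zero difference exactly is itself the transition.
* RMSE gradient uses a 1e-12 floor on the loss to avoid division by zero
  at exact fits.
* Seeds: one global seed fans out to per-stage seeds via
  `numpy.random.SeedSequence([seed, stage_tag])`; every per-image render
  uses its own spawned child stream, so datasets are bitwise reproducible
  and insensitive to generation order.

## Known limitations

* The two free kernel counts (stages 2–3) are a design choice; the kernel
  sizes alone do not pin them down.
* The adapted-threshold scan optimizes each class separately; a joint
  optimum could differ when intervals interact through overlap (not
  observed on well-separated spectra).
* Early stopping compares successive validation losses only; a
  best-so-far criterion would stop differently on noisy plateaus.
* Scores are not clipped to [−127, 127]; spectra may extend beyond the
  target range, which the calibration handles naturally.
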