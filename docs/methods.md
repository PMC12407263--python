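# Methods

This note records the models, conventions and numerical choices behind
`lfaquant`, and what the synthetic study conditions do and do not show
about real assays.

## Dose–response models and rendering

The generator emulates gold-nanoparticle LFA strips. No quantitative
transfer function from nanoparticle surface density to RGB colour is
published for this kind of assay, so the rendering chain is a package
convention built from the simplest kinetics that reproduce the known
qualitative behaviour:

- **Sandwich test line.** `S(c) = s_max · c/(k_d + c) · 1/(1 + c/hook_c)`
  — saturating capture with an optional high-dose hook. For CRP,
  `k_d = 15`, `hook_c = 10 µg/mL` put the response maximum just above
  10 µg/mL, so the signal rises through the clinically quantifiable
  window and falls beyond it (`S(5) < S(10) > S(200)`).
- **Competitive antigen line (CRP only).**
  `A(c) = a_max/(1 + c/k_c)` with `k_c = 70 µg/mL`. The constant was
  chosen once, before any end-to-end testing, by requiring the line to
  be close to log-linear over the 10–500 µg/mL branch (straight-line fit
  against log₁₀ c over the calibration levels gives R² ≈ 0.99, with
  < 10% inversion bias at 100 µg/mL), matching the near-log-linear
  behaviour such assays show over wide windows.
- **Control line.** Fixed signal (120 intensity units) independent of
  analyte; its presence defines a valid test.
- **Panel defaults.** CEA: `s_max = 180`, `k_d = 150 ng/mL` (near-linear
  over the 0–50 ng/mL window); CA-125: `s_max = 200`, `k_d = 3000 U/mL`
  (near-linear over 0–1000 U/mL); CRP as above.

Lines are rendered red-dominant (per-channel absorption weights R 0.25,
G 1.0, B 0.8 relative to the line signal), so the **green channel**
carries the strongest contrast and is the default quantification
channel. The cross-section is a flat core (nominal width 10 px) with
Gaussian shoulders (σ = width/3); the ground-truth line mask marks the
half-amplitude extent of each line whose nominal signal exceeds the
visibility floor (6 intensity units).

**Noise model** (defaults): multiplicative Gaussian on line amplitude
(σ = 5%, the dominant replicate-to-replicate term), additive per-pixel
Gaussian noise (σ = 2), a smooth linear illumination gradient (±3%),
and small line-position/width jitter (±0.8% of zone length, ±5% width).
These reproduce replicate CVs in the 4–9% range through the full
pipeline — consistent with the sub-10% replicate precision the assay
design targets — while exercising background subtraction and keeping
the segmentation task non-trivial.

**Pad scenes** composite a strip onto a textured pad with rotation
(±15°) and a lighting gain (0.7–1.3). Scenes that a gain would push
past full scale are renormalised (an auto-exposure convention: a camera
meters the frame rather than deliver a blown-out image of a white pad).
The ground-truth zone box is mapped through the exact affine used for
compositing.

What the generator does *not* model: blood staining and membrane
texture physics, perspective distortion, red-blood-cell interference,
batch-to-batch antibody variation. Passing tests therefore demonstrate
correctness of the computational chain under controlled imaging, not
robustness to every failure mode of field photographs.

## Readout pipeline

**Zone detection** is deterministic: Otsu thresholding of smoothed
brightness isolates the pale membrane (the whole frame if brightness is
near-uniform, i.e. a strip-filling image); the largest connected
component gives the box and, through its second moments, the rotation
estimate. Confidence is red-line contrast inside the box (98th
percentile of redness minus median) scaled to saturate at 1.0, and a
box is accepted iff confidence ≥ 0.8. A blank frame scores near 0 and
is rejected without raising.

**Profile extraction** takes the per-column 10%-trimmed mean of the
chosen channel (robust to specular highlights), inverts it so darker
lines become peaks, and resamples to 512 points by linear
interpolation. Background is the 20th percentile of the profile, making
line intensity (peak value minus background value) invariant to
constant offsets. Orientation is normalised by integrated contrast: the
control line sits downstream, so the downstream half is heavier; the
profile is flipped when it is not.

**Classification** counts peaks above a noise-scaled prominence floor
(`max(6σ̂, 5)` intensity units, σ̂ from the median absolute first
difference): 1 → control only, 2 → test+control, 3 →
test+antigen+control, 0 → invalid test. On the default-noise synthetic
regime this rule is exact (tested at 100% over 200 seeded samples);
harder regimes are out of the validated envelope.

## Peak segmentation model

The segmenter follows the published recipe: a fully connected network
with an input layer of 512 nodes, a hidden layer of 256 nodes (ReLU,
dropout 0.5 between layers during training), and a 1-node sigmoid
output; binary cross-entropy loss, batch size 10, 80/20 train/test
split, binarisation threshold 0.5 (a probability of exactly 0.5 counts
as peak).

The per-pixel input encodes *(position, intensity)*: the input vector
is a one-hot position vector whose active node carries
`1 + normalised intensity` (min-max per profile). Two properties follow:

- at zero intensity the input degenerates to the pure position one-hot,
  so the position prior survives faint lines — necessary to segment the
  weakest calibrated lines (normalised intensity ≈ 0.09);
- all per-position information passes through one input node, so a
  *pooled* model trained on both readout types must reconcile
  conflicting position priors (a position that is a line in three-peak
  layouts is background in two-peak layouts) using intensity alone,
  which overlaps for faint lines. Splitting by readout type before
  training therefore improves accuracy structurally — the effect the
  two-model design exists to exploit. This encoding choice is recorded
  in the model metadata (`input_encoding`) so alternatives can be
  swapped without changing the pipeline contract.

Because the mask can still propose a line slot on a strip where that
line is absent (the prior is strong by design), the pipeline accepts a
proposed segment only if its measured contrast clears the same noise
floor the classifier uses. Runs shorter than 4 px are discarded as
noise; the apex is the profile maximum within the run. Roles are
assigned to segments by nearest expected layout position
(one-to-one, Hungarian matching); the readout class fixes the expected
segment count, and a count mismatch or missing control line is an
invalid test.

Training uses Adam (lr 10⁻³, a standard choice; the source recipe fixes
only loss, epochs and batch size) with seed-controlled initialisation
(He for the ReLU layer, Glorot for the head). The default is the full
100-epoch recipe; the test suite and acceptance protocol train for 40
epochs, where convergence is already complete (held-out metrics are
unchanged between 40 and 100 epochs on the 500-profile corpora), to
keep runs short. Held-out pixelwise accuracy, precision and recall are
reported with the 0-denominator convention precision = recall = 0.

## Calibration and quantification

Calibration is ordinary least squares of replicate-mean intensity
against concentration (CEA, CA-125) or log₁₀ concentration (both CRP
branches — the assay window spans several decades and the saturating
sandwich response over 1–10 µg/mL is strongly curved in c but
near-linear in log₁₀ c). Replicates are averaged with uniform weight;
blank replicates provide µ_blank and σ_blank (sample SD). The limit of
detection is the inverse calibration of the limit of the blank,
µ_blank + 3σ_blank, floored at zero and defined for increasing
(sandwich) curves only. Intensities at or below the limit of the blank
are reported as "< LOD" rather than as negative or extrapolated
concentrations; inversions outside the fitted range are clamped and
flagged.

CRP is quantified piecewise around the 10 µg/mL hook boundary. The
branch is selected by the antigen line, which decreases monotonically
in concentration and is therefore well-posed where the test line is
not: if the measured antigen intensity is at or above the high curve's
predicted intensity at 10 µg/mL, the sample is in the sandwich regime
and the test-line curve applies on 0–10 µg/mL; otherwise the
antigen-line curve applies on 10–500 µg/mL. Both lines below the noise
floor is an invalid test.

Replicate precision is the sample-SD coefficient of variation in
percent; SNR is mean signal over the noise SD.

Clinical bands are fixed advisory thresholds: CEA normal < 5,
intermediate 5–20, elevated > 20 ng/mL; CA-125 normal ≤ 35, elevated
> 35, strongly elevated > 100 U/mL; CRP reported against the 10 µg/mL
branch boundary.

## Fluidics

The design calculator implements the three governing equations of the
capillary volume-control casing in SI units (µL/mm helpers at the CLI):
Laplace pressure of the rectangular driving channel, Hagen–Poiseuille
flow through the cylindrical capillary, and Washburn filling under
constant capillary pressure, plus reservoir fill time (volume/rate) for
the 150 µL, 60 µL and 25 µL prototype volumes. Blood is treated as
Newtonian with a configurable effective viscosity (default 4 mPa·s) —
the non-Newtonian character of whole blood is acknowledged but the
laminar design equations are applied in their Newtonian form, with the
viscosity field as the override hook. Backflow (ΔP < 0) and non-wetting
filling (θ ≥ 90° with t > 0) are rejected rather than modelled.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale corpora chosen by the package:
500 labelled profiles per variant per seed (seeds 1–3) for segmenter
evaluation, 150-profile segmenters for pipeline-level tests, 3
replicates per calibration level, 10 replicate strips per
replicate-precision condition, and 90 strips total in the acceptance
script. End-to-end recovery is asserted as the mean over 20 strips
within 15% at mid-range (CEA, CA-125) and 10 strips within 20% on the
CRP high branch, where the log-scale inversion amplifies intensity
noise. Hand-evaluated design-equation oracles are checked to 10⁻⁹
relative; the Washburn inverse is exact.

## Known limitations

- Quantification assumes reference lighting: calibration and test
  images share the rendering gain. Uncontrolled lighting gain scales
  intensities and would need a ratio normalisation (e.g. against the
  control line) that is deliberately not implemented.
- The rule-based detector and classifier are validated on the synthetic
  regime; they replace trained detectors precisely so the pipeline has
  no opaque dependencies, and they saturate only within that envelope.
- The segmenter's position prior is layout-specific: models must be
  retrained for a different strip geometry.
- Single-strip images are assumed; multiplexed dot-based layouts are
  represented in the layout type but not exercised by the pipeline.
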