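# Methods

`gazerec` implements the computational core of a looking-at-nothing retrieval
study: deciding, from eye movements alone, which of ~100 natural images a
person viewed (encoding) or mentally visualised on a blank screen (recall).
This note documents the models, the synthetic data generator that stands in
for the human dataset, the numerical choices, and what the tests do and do
not establish.

## Data model and geometry

A trial is a 5 s sequence of raw gaze samples at 1000 Hz: time (ms), screen
position (px, origin top-left, y downward), and a validity flag that is
false during blinks or track loss.  Invalid samples carry no position and
never enter any computation.  The recording geometry (0.52 m x 0.32 m screen,
1920 x 1200 px, 0.7 m viewing distance) gives per-axis pixel-to-degree
factors via the arctangent of one pixel pitch at screen distance
(~0.0222 deg/px horizontally, ~0.0218 deg/px vertically).  The factor is
treated as constant over the screen; the eccentricity error at the screen
edge is under 3 %, far below event-detection sensitivity.

## Synthetic gaze generator

The human dataset is not redistributed; the generator emulates its
statistical structure so that every downstream stage is testable, with
planted ground truth enabling parameter-recovery tests.

**Encoding.** Each image is represented by a saliency stand-in: a mixture of
2–6 bivariate Gaussians with means drawn inside the central 70 % of the
screen and axis sds of 2–8 % of screen size.  A trial draws its fixation
count from round N(16, 2.8) (clipped >= 2), fixation locations i.i.d. from
the mixture, and durations from N(278, 73.4) ms truncated at >= 50 ms.
Saccade durations follow from the main-sequence law
`V_peak = V_max (1 - e^{-A/A_0})` (defaults V_max = 500 deg/s, A_0 = 8 deg)
with a raised-cosine velocity profile, so duration = 2A/V_peak.  Fixation
durations are then rescaled (respecting the 50 ms floor) so the plan fills
the 5 s trial exactly; this shifts mean durations by a few percent at the
default counts, which we accept in exchange for non-degenerate trials.
Consecutive planted fixations are at least 30 px (~0.7 deg) apart: smaller
jumps would be microsaccades, which a fixation plan folds into one longer
fixation rather than planting as separate events.

**Rendering.** Fixations get isotropic drift with marginal sd 0.1 deg and a
~20 ms correlation time (Gaussian-kernel-smoothed white noise).  The
correlation is essential: white noise of the same amplitude at 1000 Hz
implies sample-to-sample velocities far above the 30 deg/s detection
threshold, which no fixating eye produces.  Saccades interpolate between
fixation centres with the raised-cosine profile.  Blinks (Poisson count,
mean 0.6/trial; duration N(150, 50) ms) overwrite samples as invalid.
Positions clip to the screen.

**Recall.** Recall revisits a random subset (count from round N(11, 3.6)) of
the encoding fixation locations — in random order, since imagery does not
reinstate the sequence — through a per-trial similarity transform
`x -> s (x - c) + c + tau` (c the screen centre, s uniform on [0.5, 0.95],
tau ~ N(0, 60^2 px) per axis) plus per-fixation jitter (sd 25 px), and draws
durations from N(452.2, 308.0) ms.  No quantitative distortion law is
published for imagery eye movements; the similarity-transform family is an
explicit modelling choice that captures the reported shrinkage toward the
centre, translation, and absence of consistent local distortion patterns.
A fixed per-subject multiplier on s (uniform on [0.85, 1.15]) reproduces
between-subject variation in imagery style.

**What the generator does not emulate:** image-content-driven scanpath
order, centre bias over time, saccadic undershoot/overshoot and glissades,
smooth pursuit, vergence noise, or memory decay across the session.  A green
retrieval test on synthetic data therefore establishes that the pipeline
recovers class structure under the stated noise model — not that it attains
the published human-data accuracies, which are not reproducible from
synthetic data and are used as direction/ordering properties only.

## Event detection

Velocity-based segmentation in the style of commercial parsers: the trace is
converted to degrees, boxcar-smoothed over 5 samples, and differentiated
with central differences over +/-2 samples.  A sample is saccadic when
velocity > 30 deg/s OR |acceleration| > 8000 deg/s^2.  Maximal saccadic runs
become saccades (amplitude = distance between the last sample before onset
and the first after offset; peak velocity = max smoothed speed in the run);
maximal non-saccadic valid runs >= 50 ms become fixations (position = mean
of member samples).  Sub-50 ms non-saccadic intervals *between* two saccadic
runs are folded into one movement — near saccade onset/offset the
differentiated speed briefly dips below threshold, and counting those
fragments as separate saccades would double-count.  Invalid runs padded by
+/-50 ms become blink windows that split surrounding events; a fixation
interrupted by a blink yields two fixations (no merging).  The reference
parser's smoothing and minimum fixation duration are not published; both are
configurable here, and the detector recovers planted fixation counts exactly
on >= 99 % of noise-free trials.

## Gaze-density histograms

The screen is divided into a regular G x G grid (default 24 x 24) and the
valid raw samples of a trial are counted per cell, so mass encodes dwell
time; sample order is deliberately discarded.  Cells are half-open with the
terminal screen edge closed, conserving mass at the borders.  Variants: a
binary visited-cell map, a G x G x T spatiotemporal stack (marginalising
over time reproduces the 2-D histogram exactly), and a concatenated
displacement histogram of consecutive-sample motion vectors on a centred
grid.  Networks consume histograms normalised to unit mass (decoupling them
from trial length and blink variation); kNN operates on raw counts, closest
to the counting definition.

## Retrieval methods

**kNN (baseline).** Euclidean distance on flattened histograms, k = 27,
inverse-distance vote 1/(d + 1e-8) over the k nearest.  The ROC evaluation
needs a full ranking over all classes, which a k-neighbour vote does not
define; classes with no exemplar among the k neighbours are ordered by the
distance to their nearest exemplar.  This extension reduces to the plain
weighted vote at rank 1.  Evaluation is leave-one-subject-out (LOSO) within
a phase.

**Classification CNN.** 1 x 24 x 24 input, [conv3x3 x2, maxpool] x2 with
channel widths c, 2c (default c = 32), one conv3x3 to 4c, a 256-unit
fully-connected head with batch-norm and dropout 0.5, and C logits.  The
published source describes the depth/pooling pattern but not exact layer
widths, so this architecture is an explicit stand-in.  Training:
cross-entropy, Adam (lr 5e-4, weight decay 2e-5), batch 100, 80 epochs, no
early stopping, Xavier initialisation with orthogonalised kernels where the
shape permits.  LOSO: one network per held-out subject.

**Dual-task CNN.** Same encoder; a decoder branch (conv before each
stride-2 transposed conv, final softplus for non-negativity) reconstructs
the *encoding* histogram of the same subject and image from the recall
input.  Loss `L_cross + lambda L_1` with lambda = 1000; dropout and
batch-norm are disabled everywhere in this variant.  With lambda = 0 the
training trace reduces exactly to the plain classifier's (verified bitwise
in tests).

**Triplet descriptors.** Two twin networks (classification encoder with a
16-output head, no batch-norm) embed encoding and recall histograms into a
shared 16-d space.  Two triplet losses in tandem: anchor a recall descriptor
against its matching encoding descriptor and a non-matching one, and
symmetrically with an encoding anchor.  Negatives are drawn within the
batch, a different image with the same subject preferred; margin 0.2
(unpublished; chosen as a conventional value for unit-scale embeddings).  A
contrastive pair loss is available behind `loss="hinge"`.  Training: 1000
epochs, Adam (beta1 = beta2 = 0.95), base lr 1e-3 scaled by 0.75 every 100
epochs, batch 20, L2 weight decay 1e-8.  Evaluation is 10-fold
cross-validation over images; each held-out recall descriptor is matched
within-subject against the held-out fold's encoding descriptors (candidate
set configurable to all images; the published protocol is ambiguous, and the
fold-restricted set with C = fold size is the default).

Because no deep-learning framework is assumed, the networks run on a small
numpy layer library (`gazerec.nn`) with im2col convolutions and manual
backprop; everything is float32 and bit-reproducible under a fixed seed and
single-threaded BLAS.

## Evaluation

Per query, the true image's **competition mid-rank** among all C candidates:
1 + (#strictly better) + (#tied - 1)/2, rounded half-up.  The
rank-accumulation curve plots the fraction of queries with rank <= r for
r = 0..C; **AUC** is the mean normalised rank (C - rank)/(C - 1), which is
exactly 50 % under uniform random ranks (the stated chance level) and 100 %
iff every query ranks first.  The trapezoidal area under the plotted curve
differs from this definition by at most 1/(2(C-1)) and is exposed as an
option.  Mid-rank ties keep the chance calibration unbiased.  Top-k is the
percentage of queries with rank <= k.  Per-subject AUCs weight-average back
to the pooled AUC exactly.  Phase comparisons of fixation statistics use
Welch's t (Welch–Satterthwaite df) and a two-sided Mann–Whitney U.

A caution discovered during null testing: permuting training labels and
evaluating against the *same* permuted labels yields systematically
below-chance AUC (~40 % here) — the memorised random mapping "uses up" each
query's truth label on a different image.  This is a real property of
classifier permutation nulls, not a pipeline defect.  The null calibration
therefore draws evaluation truths independently of the gaze data, for which
chance AUC is exact by construction.

## Reduced scales in the shipped tests

The full design (28 subjects x 100 images, all four methods) runs through
`gazerec run` / `run_pipeline`; CI-scale tests exercise the same code paths
with fewer subjects/images, reduced sampling rates where only counts matter,
narrower network channels, and fewer epochs (`fast` mode reduces epochs
only).  Thresholds on synthetic retrieval are direction/ordering properties;
no published human-data accuracy is asserted as a numeric target.

## Known limitations

- The CNN/descriptor architectures are stand-ins for figure-only layer
  specifications in the source publication.
- The detector is a reimplementation of a proprietary algorithm's published
  thresholds; its unpublished smoothing details are conventions.
- The recall distortion family is a modelling choice; real imagery data
  contains distortions (e.g. affine shear, content-dependent warps) it does
  not span.
- Histogram binning assumes a fixed screen; free-viewing or head-unrestrained
  data would need gaze-to-screen registration first.
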