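# Methods

## Problem setting

Acute postoperative pain in caged animals is scored behaviourally;
reduced movement is a validated indicator. The package classifies
pre-surgery ("no_pain") versus post-surgery ("pain") videos of the same
subjects, under a leave-one-subject-out protocol so that individual
identity can never substitute for the pain signal. Real footage of this
kind is noisy — cage bars, off-camera spells, motion blur, and
intermittent expression of pain — and the pipeline's design revolves
around extracting a temporal signal from single images and then
curating away the noise.

## Pipeline

### Sampling

One frame per second, taking the first frame of each second (source
index `floor(t·fps)`), truncated at 120 s. The phase within the second
is a convention, not an inference; any fixed phase would do, and the
choice is declared rather than configurable. Videos shorter than the
cap are used in full. A 7200-frame, 60 fps video therefore reduces to
120 frames.

### Detection and cropping

Detection sits behind a one-method protocol (`detect(frame) ->
Detection`) so that any external detector can drive the pipeline. Two
backends ship with the package:

* **oracle** — replays the synthetic generator's ground-truth boxes,
  decoupling pipeline behaviour from detector quality in tests;
* **background** — per-pixel median over the video's sampled frames,
  absolute difference threshold 25/255, largest 8-connected component
  (components under 9 px are ignored as speckle). By construction a
  subject that never moves is absorbed into its own background model
  and goes undetected; this limitation is intrinsic to background
  differencing and is documented and tested, not hidden.

Frames with no detection are dropped and counted per reason; counts are
conserved (`sampled = detected + dropped`) and reported with every run.
Crops expand the box by 5% per side, clip to the frame (pixels outside
the source are never read), and resize to a configurable output size
(224×224 default for encoder compatibility; the desk-scale experiments
use 32×32).

### Grayscale short-term stacking

Channel k of a stacked image holds the BT.601 luma (Y = 0.299 R +
0.587 G + 0.114 B, rounded half-up) of the crop at second t+k, with
chronological channel order (t→R, t+1→G, t+2→B) and stride-1
overlapping windows (both configurable; stride 3 gives disjoint
triplets). N sampled frames yield N−2 stacks. Windows never bridge a
gap left by a dropped frame: a stack must represent three consecutive
seconds, so surviving frames are split into consecutive runs before
windowing. The stack inherits the middle frame's timestamp. Stacking
happens after cropping; each of the three crops is resized to the
common output size first.

### Embedding

The default backend is a deterministic pixel-statistics embedder: the
image is bilinearly downsampled to a g×g raster per channel (g = 8 by
default, g = 4 in the desk-scale experiments) and flattened to [0, 1],
plus a g×g raster of the per-pixel cross-channel range. The latter
matters for the classifier head: Gaussian naive Bayes models features
independently, so a signal carried only in feature covariances (which
is where cross-channel disparity lives in the raw grid values) is
invisible to it. The dispersion raster expresses GrayST's
apparent-motion energy in feature *means*, emulating the property of a
learned encoder that visually distinct frames occupy distinct locations
in embedding space. Optional per-channel histograms can be appended.
Pretrained encoders (e.g. a 512-d contrastive vision-language model)
register under `external:<name>` behind the same two-member protocol.

### Gaussian naive Bayes head

Written from scratch: per-class log priors from counts, per-class
per-feature sample means and population variances (divide by n), a
smoothing floor of `1e-9 × max_j Var(x_j)` added to every variance, and
log-space posteriors normalized with log-sum-exp. The head is verified
in tests against a literal linear-space product of Gaussian densities
(1e-9 agreement on random small instances) and against an independent
library implementation. Probabilities are exactly invariant to joint
feature scaling and equivariant to label swaps. Models serialize to
JSON (classes, priors, moments, smoothing) for reuse across stages.

### Confidence-based frame selection

Model 1's confidence in a frame is the posterior probability of the
*video's known label* (a labelled Top-N training set per class
presupposes label-conditioned ranking). Per subject and class, frames
are ranked by confidence and the first min(N, available) kept, N = 20
by default.

Two details are deliberate:

* **Quantized ranking.** Naive Bayes posteriors are overconfident and
  uncalibrated; with a few hundred features most typical frames sit
  within float noise of probability 1. Ranking at full precision would
  order frames by artifacts of the independence approximation and
  systematically harvest the tails of each class's feature
  distribution, which demonstrably distorts the retrained model.
  Confidences are therefore quantized to 0.05 before ranking, making
  selection behave as "take the high-confidence band, earliest frames
  first". Ties resolve by earlier timestamp, then lower video id — a
  deterministic total order.
* **Per-fold selection.** Model 1, the scoring and the Top-N set are
  computed within each cross-validation fold from training subjects
  only; this is the only leakage-free reading of the protocol, and the
  audit below enforces it.

### Two-stage training and evaluation

Model 2 is fitted on the Top-N frames only and evaluated — like
Model 1 — on *all* frames of the held-out subject's videos. Validation
subjects are held aside to mirror the train/validate/test protocol; the
Gaussian head has no checkpoint to tune, so they take no part in
fitting. A video's label is the argmax of the arithmetic means of its
frames' class probabilities (average pooling); an exact tie goes to
"no_pain" — never flag pain with no evidence margin. Metrics (accuracy,
precision, recall, F1, with pain as the positive class) pool held-out
predictions across folds rather than averaging per-fold values, because
each fold contributes only two videos. Every run records SHA-256 hashes
of both models' training matrices and frame references; tests recompute
them and assert the held-out subject appears in neither.

## Synthetic study generator

The generator emulates the structure of a pre/post-surgery study: per
subject one video per class, 60 fps and 2-minute defaults, with all
parameters scaling down for desk-size experiments.

What it models, and why:

* **Subject and scene** — a textured ellipse over a static textured
  background with fixed vertical cage bars composited on top. The
  centroid follows a seeded Gaussian random walk (per-step amplitude
  4.0 px for no-pain, 0.2 px for pain by default: acute-pain animals
  are nearly immobile); the body texture scrolls and the ellipse radii
  jitter in proportion to the amplitude, so movement is visible *inside*
  a re-centred crop, as limb and posture movement is in real footage.
* **Intermittent pain expression** — pain videos spend a configurable
  fraction of time (default 0.30) in normal-looking activity bursts
  (two-state chain, ~5 s mean bout). The visible pain level of a real
  subject does not hold a fixed level throughout a recording; these
  frames carry the pain label while looking like no-pain and are
  precisely what confidence curation should discard. Baseline behaviour
  is modelled as consistent.
* **Activity-dependent noise** — motion blur (1-D box blur along the
  dominant motion axis) and heavy obstruction (a solid cage element
  hiding 40–70% of the subject, box still truthful) strike with
  probabilities scaled by instantaneous activity: both are physical
  consequences of movement. Absent/off-camera frames (background only,
  explicit absent marker) occur independently of state.
* **Appearance knob** — `appearance_shift` adds a class-conditional
  brightness offset to the subject texture. At 0 motion is the only
  class signal (the GrayST ablation condition); at 1 the shift
  dominates between-subject texture variation and the classes are
  separable from appearance alone.

Ground truth (per-frame boxes or absent markers) accompanies every
frame. Determinism: per-subject RNG streams are spawned from the master
seed, so identical configurations yield byte-identical frames and
subject content is stable under changes to the subject count.

What it does **not** model: photorealistic anatomy, facial expression
(the grimace-scale component of real pain assessment), lighting change,
camera motion, multiple animals, or re-identification risk beyond
texture idiosyncrasy. Passing tests therefore demonstrate that the
pipeline's machinery — sampling, stacking, curation, leakage-free
evaluation — behaves as designed when the class signal is behavioural
(motion), not that any particular accuracy transfers to real footage.

## Desk-scale study conditions

Experiments, examples and the acceptance script use a fixed scaled
configuration (`painpipe.presets`): 12 subjects, 4 fps, 40 s videos,
48×64 px frames, 32×32 crops, grid-4 embeddings (64 dimensions), one
validation subject per fold, N = 20. Two ratios drive these choices:
40 s at 1 Hz gives ~31 stacks per video, so Top-20 selection keeps
roughly the typically-expressed, unobstructed fraction of frames —
matching the curation role it plays at full scale — and 64 embedding
dimensions keep the retrained model's moment estimates stable at the
~400-sample size of a Top-20 training set.

Measured behaviour at these conditions (all recomputed by
`scripts/acceptance.py` and the test suite at run time): GrayST runs
reach ~0.9 video accuracy where RGB runs stay near chance when the
signal is motion-only; the retrained Model 2 matches or exceeds Model 1
in most seeded replicates; globally permuting video labels drops
accuracy to chance; the noise-free separable configuration is perfect
for both models. Two honest caveats. First, the two-stage gain here is
tie-dominated: Model 1 and Model 2 usually coincide at video level and
the mean difference is within fold-to-fold noise — the synthetic study
reproduces the qualitative ordering, not the size of the full-scale
improvement. Second, the label-permutation control sits slightly
*below* 0.5 (≈0.44): with exactly balanced labels, removing the
held-out subject tilts the training majority against it, a well-known
small-sample property of leave-one-subject-out permutation tests; the
control is asserted as a band around chance, and per-subject pair
swapping (which maximizes this anti-structure) is avoided in favour of
a global label shuffle.

## Numerical and degenerate-case conventions

* Log-space densities throughout; log-sum-exp normalization; variance
  floor as above. Fitting requires at least one sample per class and
  raises otherwise.
* Selection with fewer than N available frames keeps all of them; a
  subject-class cell with no frames is recorded as a warning and left
  empty.
* Zero-length videos sample to an empty list; fewer than three frames
  stack to an empty list; a video whose frames were all dropped raises
  an aggregation error naming the video.
* Empty metric denominators yield 0.0 with a warning rather than NaN.
* Labels are case-folded on input; unknown labels are rejected naming
  the offending manifest entry.

## Known limitations

* The background-difference detector cannot find a motionless subject;
  it exists as a desk-scale baseline and a second detector route, not
  as a substitute for a trained detector on real footage.
* Gaussian naive Bayes posteriors should be treated as scores, not
  calibrated probabilities; the selection quantization exists for this
  reason, and no calibration (Platt/temperature) is attempted.
* The pipeline performs one round of selection and retraining; it is
  not a self-training loop.
* Frame-level metrics exclude dropped frames; their videos still
  aggregate over the remaining frames.
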