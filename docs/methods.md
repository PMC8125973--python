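# Methods

`phasicpain` implements an automatic recognizer of phasic (seconds-long)
experimental pain from frontal-face video samples, together with the
synthetic cohort generator used to exercise it.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Problem setting

Each sample is a 7-second stimulus-locked recording of one subject
receiving either no stimulus (baseline, `B`) or a heat (`H`) or electrical
(`E`) stimulus at one of three individually calibrated intensities, giving
seven classes `B, H1–H3, E1–E3`.  The recognizer sees either (a) the
per-frame intensities of 17 facial action units (AU01, AU02, AU04, AU05,
AU06, AU07, AU09, AU10, AU12, AU14, AU15, AU17, AU20, AU23, AU25, AU26,
AU45, the continuous `AU*_r` outputs of an OpenFace-style extractor), or
(b) the face frames themselves.  Class balance is approximately uniform,
so accuracy is the performance measure throughout.

A central property of such data is label noise by omission: a large share
of pain samples show *no* facial reaction (low sensitivity, calibration
ceilings, individual expressiveness), so their labels cannot be recovered
from the face at all.  Several design choices below exist because of it.

## Facial Activity Descriptor (FAD)

Each AU time series is smoothed (centered moving average, default window 5
frames, edge replication) and summarized by 16 statistics computed on the
smoothed series, its first derivative and its second derivative — 48
values per series, 17 × 48 = 816 per sample.  Derivatives are forward
finite differences scaled by the frame rate, so they read as intensity per
second; time-of-extremum statistics are normalized by the series length so
they are frame-rate invariant.

The canonical statistic order is: mean, median, standard deviation,
minimum, maximum, range, interquartile range, 10th and 90th percentile,
relative time of maximum, relative time of minimum, root mean square, mean
absolute deviation, normalized trapezoidal area, least-squares slope, and
the count of strict local maxima.  The set is frozen (feature names encode
AU, level and statistic) and spans location, scale, shape and timing; any
replacement set must keep the 48-per-series layout.  Statistics are
verified against naive loop-based reference implementations at 1e-9
relative tolerance.

Degenerate inputs: a single-sample series defines the time-position
statistics and slope as 0 and the area as the sample value; series shorter
than 3 frames have no second derivative and are rejected.

## Image inputs

**Spatio-temporal image.** Three frames are taken from seconds 1, 3 and 4
of the sample — resting face, response onset and response peak for a
thermal stimulus whose plateau is reached at second 1 and whose facial
response starts roughly 2 s later.  The within-second rule is the midpoint
frame, `floor((s + 0.5)·fps)`, robust to off-by-one boundaries.  Each
frame is converted to grayscale (luma weights), resized bilinearly to
96×96, and the three are stacked as the R, G and B channels in temporal
order, so motion appears as colour.  The encoding is idempotent on
conforming input.

**Prediction image.** The forest's predicted class index 0–6 is encoded as
a constant 28×28 single-channel image with value `index/6`, exactly
invertible by rounding.  The hard label (not the score vector) is encoded
by default; a row-tiled probability-vector variant was considered and
rejected as the default because the constant image is the minimal faithful
encoding of "a number 0 to 6".  When these images accompany *training*
samples, the forest's out-of-bag predictions are used: an in-sample
prediction from a deep forest is almost always the true label, and a
network given that channel simply learns to copy it, bypassing the face
images entirely.  Test samples always get out-of-sample predictions from
the forest fitted on that fold's training data.

## Classifier families

* **RFc-BL** — random forest on the 27,648 flattened pixels of the
  spatio-temporal image (automatic baseline).
* **RFc** — random forest on the 816-component FAD vector.  Forests
  default to 5000 trees (scikit-learn, seeded); experiments at desk scale
  use far fewer, which costs little accuracy on small cohorts.
* **CNNs** — two simple CNN branches (one on the spatio-temporal image,
  one on the prediction image) fused by dense layers.  The simple CNN is
  six 3×3 convolutions with ReLU (16-16-32-32-64-64 channels), a 3×3
  stride-2 max pool after each pair, global average pooling, and a
  ReLU-activated dense layer of 1024 units.  Branch outputs are
  concatenated and passed through dense layers of 1024, 512 and 128 units
  (ReLU) to the output head.  The per-branch dense-1024 layer is kept
  before fusion (the architecture reads most naturally that way; dropping
  it would halve the fusion width and is the main alternative reading).
* **MNV2** — the image branch replaced by a reduced MobileNetV2: the
  stride-2 stem plus the first five inverted-residual blocks
  (expansion/channels/stride 1/16/1, 6/24/2, 6/24/1, 6/32/2, 6/32/1),
  batch-norm and ReLU6 throughout, then global average pooling and a
  dense-1024 layer so it is interchangeable with the simple-CNN branch.
  ImageNet initialization is supported only through an explicit weight
  file; the tested configuration is seeded random initialization.

Networks are trained with Adam (default learning rate 1e-4, batch size 64,
150 epochs; the optimizer and batch size are this package's choices) and
softmax cross-entropy.  The engine is a compact pure-NumPy implementation
(im2col convolutions backed by BLAS matmuls, float32, single-threaded),
whose gradients are verified against central finite differences; training
is deterministic given the seed.

**Multi-task variants** replace the single head with a 3-way stimulus-
modality head (`B/H/E`) plus an intensity head (0–3) that is either a
4-way softmax, a linear scalar trained with squared error, or a sigmoid
scalar (target intensity/3) trained with cross-entropy.  Head losses are
summed with equal weights.  For 7-class evaluation the heads are combined:
P(intensity 0) maps to baseline, painful intensities split across H/E by
the renormalized modality probabilities; scalar intensity outputs are
rounded to the nearest level first, and a baseline-modality prediction
with a painful intensity falls back to the more probable painful modality
(H on exact ties, matching the global class order).

## Sample weighting

After training a model on a training fold, every training sample whose
classification score exceeds 0.3 is duplicated once, and the model is
retrained on the extended set.  The score is the model's probability for
the *ground-truth* class (default): the goal is upweighting samples whose
true pain reaction is learnable, whereas the top-1 probability would also
upweight confidently wrong samples (`score="max_prob"` implements that
alternative reading).  This is deliberately the opposite of hard-example
mining — under response-free label noise it is more valuable to reduce
the influence of unlearnable samples than to hammer on them.  Scoring
models are always fitted on the same training fold they score, never on
test data, and an integrity guard asserts that no test set contains
duplicated ids.  Test data is never modified.

## Evaluation harness

Seven tasks are evaluated: the 7-class task, two 5-class tasks
(`B,E1,H1,E3,H3` and `B,E2,H2,E3,H3`) and four single-modality 3-class
tasks (`B,E1,E3`, `B,E2,E3`, `B,H1,H3`, `B,H2,H3`).  Cross-validation is
stratified 5-fold without subject overlap (grouped stratification via
scikit-learn's `StratifiedGroupKFold`); subject disjointness is asserted
on every run.  The headline accuracy pools the concatenated fold
predictions; the mean of per-fold accuracies is reported alongside, since
the two can differ on uneven folds.  A fold missing a task class is kept
with a logged warning rather than re-randomized, for determinism.

The trivial baseline predicts the training fold's majority class (lowest
class index on ties); on balanced data it scores exactly 1/n-classes.

The observer subset draws a class-balanced 10% of samples:
`round(0.1 · n_class)` per class, spread one-at-a-time across that class's
subject cells in seeded round-robin order.  (Per-cell rounding — 10% of
each subject-class cell — collapses to zero for small cells; the per-class
quota keeps the intended class balance at any cohort size.)

Two predictors are compared on a common subset by per-subject accuracy —
subjects, not samples, are the exchangeable unit under subject-disjoint
CV — with a two-sided paired t-test; a per-sample McNemar test is
reported as a secondary check.  Identical predictors are defined to give
p = 1 (the t statistic is 0/0 there).

## Synthetic cohort generator

The generator emulates the statistical skeleton of the study:

* **Cohort.**  Default 127 subjects.  Expressiveness is lognormal (median
  1, log-sd 0.4); 5% of subjects are non-responders (expressiveness 0).
  Response probabilities per intensity have means (0.45, 0.60, 0.75) with
  a subject-level offset (sd 0.15), clipped to [0,1] and made monotone in
  intensity — so on average about 40% of pain samples carry *no* facial
  response, the noise regime the weighting method targets.
* **Series.**  17 AU channels at 25 fps for 7 s (the camera rate is a
  package default; it is configurable).  Baseline is smoothed, zero-
  clipped Gaussian noise (sd per subject in [0.10, 0.30]) around a small
  resting offset.  A responding pain sample adds a gamma-shaped bump to
  the pain-related AUs (AU04, AU06, AU07, AU09, AU10, AU45, with weights
  1.0…0.5), amplitude proportional to felt intensity × expressiveness
  with lognormal jitter.
* **Modality asymmetry.**  Electrical responses are earlier, steeper and
  tightly time-locked: onset ~1 s after stimulus start (latency jitter sd
  0.15 s), rise to peak in 0.6 s.  Heat responses are later, slower and
  loosely time-locked: onset ~3 s (jitter sd 0.8 s, so late responses are
  partially truncated by the 7-s window), rise 1.0 s.  In addition, 30%
  of subjects model the thermal safety cutoff: their felt heat intensity
  saturates at level 2, so H3 stops being separable from H2 for them
  (electrical stimulation has no cap).  Together these make the
  electrical 3-class tasks at least as recognisable as the heat tasks,
  the asymmetry the evaluation harness checks.  An early parameterization
  with a much wider heat bump (rise 1.5 s) buried this asymmetry under
  heat's larger integrated signal; the bump widths were brought closer
  (1.0 s vs 0.6 s) so the designed timing/cap mechanisms, not an
  accidental area advantage, determine the contrast.
* **Frames.**  A schematic parametric face (brows, eyes, nasolabial
  furrows, mouth) deformed per-frame by the AU values.  It is a stand-in,
  not a photorealistic renderer: it shows that the image pipeline can
  extract class signal from facial geometry, nothing more.

All generators are pure functions of seed and configuration; datasets are
byte-identical across runs.  What passing tests on this cohort shows: the
pipeline's contracts hold, uninformative data yields chance, informative
data is recovered, and the weighting and modality effects point the right
way under the stated noise model.  What they do not show: performance on
real faces, real AU-extractor noise, head pose, occlusion, or identity
leakage through appearance.

## Desk-scale experiment sizes

The test and acceptance experiments run on reduced problem sizes chosen as
this package's defaults for single-CPU runs: cohorts of 10–30 subjects
with 2–4 samples per class, forests of 30–200 trees, CNN schedules of
8–15 epochs at batch 16 with 16–24-pixel renderings, and 5 seeds for
directional claims.  The qualitative findings these runs reproduce —
above-chance recognition, weighting benefit under noise, electrical >
heat — are stable at these sizes; absolute accuracies are not comparable
to a 127-subject cohort and are not asserted anywhere.

## Known limitations

* The exact statistic set of the original 48-component descriptor is
  defined in prior work; the 16-statistic set here is a documented,
  version-frozen stand-in with the same shape and intent.
* The smoothing referenced by the descriptor literature is likewise not
  restated there; a centered moving average stands in for it.
* The NumPy network engine is single-threaded and CPU-bound; it is meant
  for desk-scale experiments, not for training at full study scale.
* The schematic face renderer cannot model appearance variation between
  subjects, so image-branch results on synthetic data are optimistic about
  identity robustness.
* Multi-task variants are implemented and tested for contract and
  learnability, but no claim is made that they outperform single-task
  training (they did not in the experiments that motivated them either).
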