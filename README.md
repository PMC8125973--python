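# phasicpain

Automatic recognition of phasic (seconds-long) experimental pain intensity
from facial activity, for researchers studying machine-versus-human pain
assessment.  Each 7-second video sample of a subject receiving no stimulus
(baseline `B`) or a heat/electrical stimulus at one of three calibrated
intensities (`H1–H3`, `E1–E3`) is classified into one of those seven
classes — a deliberately hard task, because a large share of pain samples
show no facial reaction at all.

The package provides, as a tested pipeline:

* **FAD features** — each of 17 action-unit intensity time series
  (OpenFace-style `AU*_r` outputs) is smoothed and summarized by 16
  statistics of the series, its first and its second derivative: a
  48-component descriptor per series, 816 per sample;
* **spatio-temporal images** — grayscale frames from seconds 1, 3 and 4,
  resized to 96×96 and stacked as the R/G/B channels of one image, plus a
  constant 28×28 *prediction image* encoding a random forest's predicted
  class 0–6;
* **four classifier families** — random forests on flattened pixels
  (RFc-BL) or on FAD vectors (RFc), and two-branch CNN fusions (simple CNN
  × simple CNN, or a reduced MobileNetV2 × simple CNN) with optional
  multi-task heads (stimulus modality + intensity), built on a compact
  seeded pure-NumPy network engine;
* **duplication weighting** — training samples whose classification score
  exceeds 0.3 are duplicated once (the opposite of hard-example mining:
  it downweights the unlearnable, reaction-free samples); test sets are
  guarded against any contamination;
* **an evaluation harness** — seven classification tasks, stratified
  5-fold cross-validation without subject overlap, a majority-class
  trivial baseline, a class-balanced 10% observer subset draw, and paired
  t-test comparison of any two predictors, including human-observer label
  files;
* **a synthetic cohort generator** that emulates the restricted study
  data: subject-specific expressiveness, ~40% of pain samples without a
  facial response, and earlier/steeper responses to electrical than to
  heat stimuli, with schematic face frames for the image branch.

## Worked example

```python
import phasicpain as pp
from phasicpain.models import ArchitectureSpec

ds = pp.generate_dataset(n_subjects=12, reps_per_class=2, seed=42)

trivial = pp.trivial_baseline("7class", ds, seed=0)
arch = ArchitectureSpec(kind="rfc_fad", n_trees=300)
res = pp.run_cv("7class", arch, ds, seed=0)

print(f"trivial baseline: {trivial.pooled_accuracy:.3f}")
print(f"RFc on FAD, 7-class: pooled {res.pooled_accuracy:.3f}, "
      f"fold mean {res.mean_fold_accuracy:.3f}")
print(res.confusion)
```

Output:

```
trivial baseline: 0.143
RFc on FAD, 7-class: pooled 0.458, fold mean 0.464
pred   B  H1  H2  H3  E1  E2  E3
true
B     19   0   0   0   4   1   0
H1     8  12   3   0   1   0   0
H2     3   7   1   9   3   1   0
H3     3   3   2  16   0   0   0
E1    10   0   0   0  10   3   1
E2     7   0   0   0   6   3   8
E3     1   0   0   0   2   5  16
```

The trivial baseline sits at chance (1/7 ≈ 0.143).  The forest on FAD
features reaches 0.458 on this small synthetic cohort — well above chance
but far from perfect, and the confusion matrix shows why: low-intensity
pain (`H1`, `E1`, `E2`) is persistently confused with baseline, the
signature of samples without observable facial reactions.  Note that
synthetic-cohort accuracies are not comparable to real-study numbers.

The same harness runs the CNN fusions and the weighting contrast, e.g.

```python
arch = ArchitectureSpec(kind="cnns_fusion", epochs=8, batch_size=16, image_size=24)
base, weighted, plans = pp.weighting_experiment("7class", arch, ds, seed=0)
```

A CLI mirrors the stages (`phasicpain --config cfg.yaml simulate`,
`features`, `preprocess`, `train`, `weight`, `evaluate`, `compare-human`,
`report`); every stage writes its resolved configuration next to its
artifacts.

## Layout

```
src/phasicpain/
  synthetic.py     cohort generator and schematic face renderer
  io.py            AU CSVs, manifests, labels, fold plans, results
  preprocess.py    frame selection, spatio-temporal + prediction images, smoothing
  fad.py           the 48-per-series / 816-per-sample descriptor
  nn/              NumPy network engine (conv, depthwise, batchnorm, Adam)
  models.py        RFc-BL, RFc, CNNs fusion, reduced-MNV2 fusion, MTL heads
  weighting.py     score-threshold duplication weighting + integrity guard
  evaluation.py    tasks, subject-disjoint CV, baselines, observer subset, t-tests
  cli.py           staged command-line front end
docs/methods.md    models, parameters, numerical choices, limitations
```
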