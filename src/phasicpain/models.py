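"""The four classifier families of the recognition pipeline.

* ``rfc_bl`` — random forest on flattened spatio-temporal pixel images (the
  automatic baseline);
* ``rfc_fad`` — random forest on the 816-component facial-activity
  descriptor;
* ``cnns_fusion`` — two simple CNN branches (spatio-temporal image +
  forest-prediction image) fused by a 1024/512/128 dense trunk;
* ``mnv2_fusion`` — like ``cnns_fusion`` but with a reduced MobileNetV2
  (stem plus the first 5 inverted residual blocks) as the image branch.

CNN variants optionally carry multi-task heads: a 3-way stimulus-modality
head (B/H/E) plus an intensity head that is either a 4-way softmax, a
linear scalar trained with squared error, or a sigmoid scalar trained with
cross-entropy.  All families share one train/predict contract: per-class
scores are non-negative and sum to 1, and the hard label is the argmax
(lowest index wins ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .constants import CLASSES, MODALITIES, split_class

__all__ = [
    "ArchitectureSpec",
    "TrainingError",
    "ForestModel",
    "CNNModel",
    "build_simple_cnn",
    "build_reduced_mnv2",
    "build_fusion",
    "train_forest",
    "train_cnn",
    "predict",
    "hard_labels",
    "combine_mtl",
]

FOREST_KINDS = ("rfc_bl", "rfc_fad")
CNN_KINDS = ("mnv2_fusion", "cnns_fusion")
MTL_VARIANTS = ("none", "softmax_softmax", "softmax_mse", "softmax_sigmoid")


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ArchitectureSpec:
    """Configuration of one classifier family."""

    kind: str
    mtl_variant: str = "none"
    n_trees: int = 5000
    epochs: int = 150
    learning_rate: float = 1e-4
    batch_size: int = 64
    pretrained_backbone: bool = False
    image_size: int = 96

    def __post_init__(self) -> None:
        if self.kind not in FOREST_KINDS + CNN_KINDS:
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if self.mtl_variant not in MTL_VARIANTS:
            raise ValueError(f"unknown MTL variant {self.mtl_variant!r}")
        if self.mtl_variant != "none" and self.kind not in CNN_KINDS:
            raise ValueError("multi-task heads are only valid for CNN architectures")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def _check_pool_depth(height: int, width: int) -> None:
    side = min(height, width)
    p1 = (side - 3) // 2 + 1 if side >= 3 else 0
    p2 = (p1 - 3) // 2 + 1 if p1 >= 3 else 0
    if p2 < 2:
        raise ValueError(
            f"input {height}x{width} is too small for two 3x3/stride-2 max pools"
        )


def build_simple_cnn(input_shape: tuple[int, int, int]) -> nn.Sequential:
    """The simple CNN branch.

    Six 3x3 convolutions, each followed by ReLU; channel widths
    16-16-32-32-64-64 with a 3x3/stride-2 max pool after every pair;
    global average pooling; one ReLU-activated dense layer with 1024
    neurons as the branch feature output.
    """
    height, width, channels = input_shape
    if channels not in (1, 3):
        raise ValueError("input must have 1 or 3 channels")
    _check_pool_depth(height, width)
    layers = [
        nn.Conv2D(channels, 16), nn.ReLU(),
        nn.Conv2D(16, 16), nn.ReLU(),
        nn.MaxPool2D(3, 2),
        nn.Conv2D(16, 32), nn.ReLU(),
        nn.Conv2D(32, 32), nn.ReLU(),
        nn.MaxPool2D(3, 2),
        nn.Conv2D(32, 64), nn.ReLU(),
        nn.Conv2D(64, 64), nn.ReLU(),
        nn.GlobalAvgPool(),
        nn.Dense(64, 1024), nn.ReLU(),
    ]
    net = nn.Sequential(layers)
    net.feature_width = 1024
    return net


#: (expansion factor, output channels, stride) of the first five
#: MobileNetV2 inverted-residual (bottleneck) blocks.
MNV2_BLOCK_CONFIG: tuple[tuple[int, int, int], ...] = (
    (1, 16, 1), (6, 24, 2), (6, 24, 1), (6, 32, 2), (6, 32, 1),
)


def _inverted_residual(cin: int, expansion: int, cout: int, stride: int):
    mid = cin * expansion
    layers: list[nn.Sequential | object] = []
    if expansion != 1:
        layers += [nn.Conv2D(cin, mid, kernel=1, pad=0, bias=False),
                   nn.BatchNorm2D(mid), nn.ReLU6()]
    layers += [
        nn.DepthwiseConv2D(mid, kernel=3, stride=stride, pad=1),
        nn.BatchNorm2D(mid), nn.ReLU6(),
        nn.Conv2D(mid, cout, kernel=1, pad=0, bias=False),
        nn.BatchNorm2D(cout),
    ]
    block = nn.Sequential(layers)
    if stride == 1 and cin == cout:
        return nn.Residual(block)
    return block


def build_reduced_mnv2(pretrained: bool = False, input_channels: int = 3,
                       weights_file: str | None = None) -> nn.Sequential:
    """Reduced MobileNetV2 image branch: 3x3/stride-2 stem (32 channels,
    batch-norm, ReLU6) plus the first 5 inverted residual blocks, then
    global average pooling and a ReLU dense layer of width 1024 so the
    branch is interchangeable with the simple CNN downstream.

    ``pretrained=True`` requires an explicit ``weights_file``; the default
    is seeded random initialization.
    """
    if pretrained and weights_file is None:
        raise ValueError(
            "pretrained_backbone requested but no weights_file given; "
            "pass a weight file or use random initialization"
        )
    layers = [nn.Conv2D(input_channels, 32, kernel=3, stride=2, pad=1, bias=False),
              nn.BatchNorm2D(32), nn.ReLU6()]
    cin = 32
    for expansion, cout, stride in MNV2_BLOCK_CONFIG:
        layers.append(_inverted_residual(cin, expansion, cout, stride))
        cin = cout
    layers += [nn.GlobalAvgPool(), nn.Dense(cin, 1024), nn.ReLU()]
    net = nn.Sequential(layers)
    net.feature_width = 1024
    net.n_inverted_residual_blocks = len(MNV2_BLOCK_CONFIG)
    if weights_file is not None:
        _load_weights(net, weights_file)
    return net


def _load_weights(net: nn.Sequential, path: str) -> None:
    data = np.load(path)
    params = net.params
    if len(data.files) != len(params):
        raise ValueError(f"{path}: expected {len(params)} arrays, got {len(data.files)}")
    for key, p in zip(data.files, params):
        p.value[...] = data[key]


def build_fusion(image_branch: nn.Sequential, prediction_branch: nn.Sequential,
                 n_classes: int, mtl_variant: str = "none") -> nn.FusionNet:
    """Fuse two branches with the 1024/512/128 dense trunk and attach heads."""
    if mtl_variant not in MTL_VARIANTS:
        raise ValueError(f"unknown MTL variant {mtl_variant!r}")
    widths = [image_branch.feature_width, prediction_branch.feature_width]
    trunk = nn.Sequential([
        nn.Dense(sum(widths), 1024), nn.ReLU(),
        nn.Dense(1024, 512), nn.ReLU(),
        nn.Dense(512, 128), nn.ReLU(),
    ])
    from .nn.net import Head

    if mtl_variant == "none":
        heads = [Head(128, n_classes, "softmax", "classes")]
    else:
        intensity_kind = {"softmax_softmax": ("softmax", 4),
                          "softmax_mse": ("linear", 1),
                          "softmax_sigmoid": ("sigmoid", 1)}[mtl_variant]
        heads = [Head(128, 3, "softmax", "modality"),
                 Head(128, intensity_kind[1], intensity_kind[0], "intensity")]
    return nn.FusionNet([image_branch, prediction_branch], trunk, heads, widths)


# ---------------------------------------------------------------------------
# trained-model wrappers
# ---------------------------------------------------------------------------

class ForestModel:
    """Random forest with the shared score-matrix predict contract."""

    def __init__(self, spec: ArchitectureSpec, forest: RandomForestClassifier,
                 class_list: tuple[str, ...]):
        self.spec = spec
        self.forest = forest
        self.class_list = tuple(class_list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        proba = self.forest.predict_proba(features)
        scores = np.zeros((features.shape[0], len(self.class_list)))
        for j, cls in enumerate(self.forest.classes_):
            scores[:, self.class_list.index(cls)] = proba[:, j]
        return scores


class CNNModel:
    """Trained fusion network with the shared predict contract.

    For multi-task variants, per-class scores are derived from the heads:
    the intensity head supplies P(intensity), with P(intensity 0) mapping
    to baseline and painful intensities splitting across H/E according to
    the modality head (renormalized).  Scalar intensity heads are rounded
    to the nearest intensity before mapping.
    """

    def __init__(self, spec: ArchitectureSpec, net: nn.FusionNet,
                 class_list: tuple[str, ...], loss_history: list[float]):
        self.spec = spec
        self.net = net
        self.class_list = tuple(class_list)
        self.loss_history = loss_history

    def predict_heads(self, inputs, batch_size: int = 128) -> list[np.ndarray]:
        xs = [_to_nchw(x) for x in inputs]
        n = xs[0].shape[0]
        outs: list[list[np.ndarray]] = []
        for start in range(0, n, batch_size):
            batch = [x[start:start + batch_size] for x in xs]
            outs.append(self.net.predict(batch))
        return [np.concatenate([o[i] for o in outs]) for i in range(len(outs[0]))]

    def predict(self, inputs) -> np.ndarray:
        heads = self.predict_heads(inputs)
        if self.spec.mtl_variant == "none":
            return heads[0]
        return self._mtl_scores(heads)

    def _mtl_scores(self, heads: list[np.ndarray]) -> np.ndarray:
        p_mod, intensity_out = heads
        n = p_mod.shape[0]
        if self.spec.mtl_variant == "softmax_softmax":
            p_int = intensity_out
        else:
            # scalar intensity -> degenerate (one-hot) intensity distribution
            if self.spec.mtl_variant == "softmax_mse":
                level = np.clip(np.rint(intensity_out[:, 0]), 0, 3).astype(int)
            else:  # sigmoid scalar encodes intensity/3
                level = np.clip(np.rint(intensity_out[:, 0] * 3), 0, 3).astype(int)
            p_int = np.zeros((n, 4))
            p_int[np.arange(n), level] = 1.0
        scores = np.zeros((n, len(self.class_list)))
        i_h, i_e = MODALITIES.index("H"), MODALITIES.index("E")
        pain_mod = p_mod[:, [i_h, i_e]]
        pain_mod = pain_mod / np.maximum(pain_mod.sum(axis=1, keepdims=True), 1e-12)
        for j, cls in enumerate(self.class_list):
            mod, level = split_class(cls)
            if level == 0:
                scores[:, j] = p_int[:, 0]
            else:
                col = 0 if mod == "H" else 1
                scores[:, j] = p_int[:, level] * pain_mod[:, col]
        return scores / scores.sum(axis=1, keepdims=True)


def _to_nchw(x: np.ndarray) -> np.ndarray:
    from .nn.layers import DTYPE

    x = np.asarray(x, dtype=DTYPE)
    if x.ndim == 3:  # (N,H,W) -> single channel
        x = x[:, :, :, None]
    return np.transpose(x, (0, 3, 1, 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_forest(features: np.ndarray, labels, n_trees: int = 5000,
                 seed: int = 0, spec: ArchitectureSpec | None = None,
                 class_list: tuple[str, ...] | None = None,
                 oob: bool = False) -> ForestModel:
    """Fit a random forest on a feature matrix (FAD vectors or flattened
    spatio-temporal pixels).

    ``oob=True`` additionally keeps out-of-bag scores, used when forest
    predictions of its own training data must not simply echo the labels.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    present = sorted(set(labels))
    if len(present) < 2:
        raise TrainingError("training set contains a single class")
    if features.shape[0] < len(present):
        raise TrainingError("fewer training rows than classes")
    spec = spec or ArchitectureSpec(kind="rfc_fad", n_trees=n_trees)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    oob_score=oob)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # tiny forests can leave a few samples with no out-of-bag trees;
        # those rows are handled downstream
        _warnings.simplefilter("ignore", UserWarning)
        forest.fit(features, labels)
    cl = tuple(class_list) if class_list else tuple(c for c in CLASSES if c in present)
    return ForestModel(spec, forest, cl)


def oob_scores(model: ForestModel) -> np.ndarray:
    """Out-of-bag per-class scores of a forest's own training samples,
    aligned to ``model.class_list``; rows with no out-of-bag trees fall
    back to a uniform distribution."""
    forest = model.forest
    if not getattr(forest, "oob_score", False):
        raise ValueError("forest was trained without oob_score")
    raw = forest.oob_decision_function_
    scores = np.zeros((raw.shape[0], len(model.class_list)))
    for j, cls in enumerate(forest.classes_):
        scores[:, model.class_list.index(cls)] = raw[:, j]
    empty = ~np.isfinite(scores).all(axis=1) | (scores.sum(axis=1) < 1e-9)
    scores[empty] = 1.0 / len(model.class_list)
    return scores


def _build_net(spec: ArchitectureSpec, image_shape, n_classes: int) -> nn.FusionNet:
    if spec.kind == "cnns_fusion":
        image_branch = build_simple_cnn(image_shape)
    elif spec.kind == "mnv2_fusion":
        image_branch = build_reduced_mnv2(pretrained=spec.pretrained_backbone,
                                          input_channels=image_shape[2])
    else:
        raise ValueError(f"{spec.kind!r} is not a CNN architecture")
    prediction_branch = build_simple_cnn((28, 28, 1))
    return build_fusion(image_branch, prediction_branch, n_classes, spec.mtl_variant)


def _cnn_targets(spec: ArchitectureSpec, labels, class_list) -> list[np.ndarray]:
    labels = list(labels)
    if spec.mtl_variant == "none":
        index = {c: i for i, c in enumerate(class_list)}
        return [np.array([index[c] for c in labels], dtype=int)]
    mods, levels = zip(*(split_class(c) for c in labels))
    mod_idx = np.array([MODALITIES.index(m) for m in mods], dtype=int)
    levels = np.array(levels, dtype=float)
    if spec.mtl_variant == "softmax_softmax":
        return [mod_idx, levels.astype(int)]
    if spec.mtl_variant == "softmax_mse":
        return [mod_idx, levels]
    return [mod_idx, levels / 3.0]  # sigmoid target in [0, 1]


def train_cnn(spec: ArchitectureSpec, inputs, labels, seed: int = 0,
              class_list: tuple[str, ...] | None = None,
              epochs: int | None = None, lr: float | None = None) -> CNNModel:
    """Train a fusion network on paired (spatio-temporal, prediction) images.

    ``inputs`` is a pair of NHWC arrays.  Mini-batches are reshuffled every
    epoch from the seed; with ``epochs=0`` the model is returned at its
    (seeded) initialization.  A non-finite loss aborts with diagnostics.
    """
    if spec.kind not in CNN_KINDS:
        raise ValueError(f"train_cnn needs a CNN architecture, got {spec.kind!r}")
    x_img, x_pred = (np.asarray(x, dtype=float) for x in inputs)
    if x_img.shape[0] != x_pred.shape[0]:
        raise ValueError("branch inputs must have equal sample counts")
    labels = np.asarray(labels)
    cl = tuple(class_list) if class_list else tuple(c for c in CLASSES if c in set(labels))
    epochs = spec.epochs if epochs is None else epochs
    lr = spec.learning_rate if lr is None else lr

    image_shape = x_img.shape[1:] if x_img.ndim == 4 else (*x_img.shape[1:], 1)
    net = _build_net(spec, image_shape, len(cl))
    net.initialize(seed)
    targets = _cnn_targets(spec, labels, cl)
    xa, xb = _to_nchw(x_img), _to_nchw(x_pred)

    optimizer = nn.Adam(net.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = xa.shape[0]
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            batch_targets = [t[idx] for t in targets]
            loss = net.train_step([xa[idx], xb[idx]], batch_targets, optimizer)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch offset {start} "
                    f"(lr={lr}, batch_size={spec.batch_size})"
                )
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
    return CNNModel(spec, net, cl, history)


# ---------------------------------------------------------------------------
# prediction helpers
# ---------------------------------------------------------------------------

def predict(model, inputs) -> np.ndarray:
    """Per-class score matrix (rows sum to 1) for any trained model."""
    return model.predict(inputs)


def hard_labels(scores: np.ndarray, class_list) -> list[str]:
    """Argmax class codes; ties resolve to the lowest class index."""
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[1] != len(class_list):
        raise ValueError(
            f"score matrix must be (n, {len(class_list)}), got {scores.shape}"
        )
    return [class_list[i] for i in scores.argmax(axis=1)]


def combine_mtl(modality: str, intensity: int,
                modality_scores: np.ndarray | None = None) -> str:
    """Map multi-task head outputs to a 7-class code.

    Baseline if and only if the intensity is 0.  If the modality head says
    baseline while the intensity head says pain, the more probable painful
    modality wins (H on ties or when no scores are given).
    """
    intensity = int(intensity)
    if not 0 <= intensity <= 3:
        raise ValueError("intensity must be in 0..3")
    if intensity == 0:
        return "B"
    if modality in ("H", "E"):
        return f"{modality}{intensity}"
    if modality_scores is not None:
        i_h, i_e = MODALITIES.index("H"), MODALITIES.index("E")
        modality = "E" if modality_scores[i_e] > modality_scores[i_h] else "H"
    else:
        modality = "H"
    return f"{modality}{intensity}"
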