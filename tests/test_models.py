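import numpy as np
import pytest

from phasicpain import fad, models
from phasicpain.constants import CLASSES
from phasicpain.models import (
    ArchitectureSpec,
    TrainingError,
    build_fusion,
    build_reduced_mnv2,
    build_simple_cnn,
    combine_mtl,
    hard_labels,
    train_cnn,
    train_forest,
)


class TestArchitectureSpec:
    def test_mtl_only_for_cnns(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(kind="rfc_fad", mtl_variant="softmax_softmax")

    @pytest.mark.parametrize("bad", [{"kind": "lstm"}, {"kind": "rfc_fad", "n_trees": 0}])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            ArchitectureSpec(**bad)


class TestBuilders:
    def test_simple_cnn_feature_widths(self):
        net = build_simple_cnn((96, 96, 3))
        net.initialize(np.random.default_rng(0))
        out = net.forward(np.zeros((1, 3, 96, 96), dtype=np.float32))
        assert out.shape == (1, 1024)

    def test_simple_cnn_gap_width_on_small_input(self):
        net = build_simple_cnn((28, 28, 1))
        net.initialize(np.random.default_rng(0))
        # feature before the dense layer is the 64-channel GAP output
        x = np.random.default_rng(1).random((2, 1, 28, 28)).astype(np.float32)
        for layer in net.layers[:-2]:
            x = layer.forward(x)
        assert x.shape == (2, 64)

    def test_simple_cnn_rejects_tiny_input(self):
        with pytest.raises(ValueError, match="too small"):
            build_simple_cnn((8, 8, 1))

    def test_reduced_mnv2_has_five_blocks(self):
        net = build_reduced_mnv2()
        assert net.n_inverted_residual_blocks == 5

    def test_mnv2_interchangeable_with_simple_cnn(self):
        # both image branches satisfy the same downstream contract
        for branch in (build_simple_cnn((64, 64, 3)), build_reduced_mnv2()):
            pred = build_simple_cnn((28, 28, 1))
            net = build_fusion(branch, pred, n_classes=7)
            net.initialize(3)
            out = net.predict([
                np.zeros((2, 3, 64, 64), dtype=np.float32),
                np.zeros((2, 1, 28, 28), dtype=np.float32),
            ])
            assert out[0].shape == (2, 7)

    def test_pretrained_without_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            build_reduced_mnv2(pretrained=True)

    @pytest.mark.parametrize("variant,widths", [
        ("none", [7]),
        ("softmax_softmax", [3, 4]),
        ("softmax_mse", [3, 1]),
        ("softmax_sigmoid", [3, 1]),
    ])
    def test_head_widths_per_variant(self, variant, widths):
        net = build_fusion(build_simple_cnn((32, 32, 3)),
                           build_simple_cnn((28, 28, 1)), 7, variant)
        assert [h.width for h in net.heads] == widths
        if variant == "softmax_mse":
            assert net.heads[1].kind == "linear"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_fusion(build_simple_cnn((32, 32, 3)),
                         build_simple_cnn((28, 28, 1)), 7, "softmax_poisson")


@pytest.fixture(scope="module")
def separable_features():
    """Two linearly separable classes in FAD-like feature space."""
    rng = np.random.default_rng(0)
    x0 = rng.normal(0.0, 0.3, size=(30, 20))
    x1 = rng.normal(3.0, 0.3, size=(30, 20))
    x = np.vstack([x0, x1])
    y = ["B"] * 30 + ["E3"] * 30
    return x, y


class TestForest:
    def test_separable_training_accuracy(self, separable_features):
        x, y = separable_features
        model = train_forest(x, y, n_trees=50, seed=0)
        preds = hard_labels(model.predict(x), model.class_list)
        assert preds == y

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train_forest(np.zeros((10, 4)), ["B"] * 10, n_trees=5)

    def test_ensemble_monotonicity(self, noisy_dataset):
        """More trees do at least as well as a single tree on average."""
        features = fad.feature_matrix(list(noisy_dataset.samples.values())[:100])
        labels = [noisy_dataset.sample(s).label for s in features.index]
        x = features.to_numpy()
        accs = {1: [], 60: []}
        for seed in range(5):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(labels))
            split = int(0.7 * len(idx))
            tr, te = idx[:split], idx[split:]
            y = np.array(labels)
            for n in accs:
                m = train_forest(x[tr], y[tr], n_trees=n, seed=seed,
                                 class_list=CLASSES)
                pred = hard_labels(m.predict(x[te]), CLASSES)
                accs[n].append(float((np.array(pred) == y[te]).mean()))
        assert np.mean(accs[60]) >= np.mean(accs[1]) - 1e-9

    def test_scores_sum_to_one(self, separable_features):
        x, y = separable_features
        model = train_forest(x, y, n_trees=20, seed=1)
        scores = model.predict(np.random.default_rng(2).normal(size=(40, 20)))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        assert (scores >= 0).all()


@pytest.fixture(scope="module")
def image_pair_problem():
    """Two visually distinct classes rendered as images."""
    rng = np.random.default_rng(0)
    n = 40
    ximg = rng.random((n, 16, 16, 3)) * 0.1
    ximg[n // 2:] += 0.8  # bright class vs dark class
    xpred = np.zeros((n, 28, 28, 1))
    y = ["B"] * (n // 2) + ["E3"] * (n // 2)
    return (ximg, xpred), y


class TestCNNTraining:
    def test_learns_separable_images(self, image_pair_problem):
        inputs, y = image_pair_problem
        spec = ArchitectureSpec(kind="cnns_fusion", epochs=10, batch_size=8,
                                learning_rate=1e-3, image_size=16)
        model = train_cnn(spec, inputs, y, seed=0)
        preds = hard_labels(model.predict(inputs), model.class_list)
        acc = float(np.mean(np.array(preds) == np.array(y)))
        assert acc > 0.9
        # trailing training loss went down
        assert model.loss_history[-1] < model.loss_history[0]

    def test_zero_epochs_stays_at_initialization(self, image_pair_problem):
        inputs, y = image_pair_problem
        spec = ArchitectureSpec(kind="cnns_fusion", epochs=0, image_size=16)
        model = train_cnn(spec, inputs, y, seed=0)
        assert model.loss_history == []
        scores = model.predict(inputs)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-5)

    def test_mtl_heads_learn_above_chance(self):
        rng = np.random.default_rng(1)
        labels = [c for c in CLASSES for _ in range(8)]
        n = len(labels)
        # encode class identity directly into image brightness pattern
        ximg = np.zeros((n, 16, 16, 3))
        for i, c in enumerate(labels):
            ximg[i, :, :, :] = CLASSES.index(c) / 6
        ximg += rng.normal(0, 0.02, ximg.shape)
        xpred = np.zeros((n, 28, 28, 1))
        spec = ArchitectureSpec(kind="cnns_fusion", mtl_variant="softmax_softmax",
                                epochs=15, batch_size=8, learning_rate=1e-3,
                                image_size=16)
        model = train_cnn(spec, (ximg, xpred), labels, seed=0)
        p_mod, p_int = model.predict_heads((ximg, xpred))
        from phasicpain.constants import MODALITIES, split_class

        mods = np.array([MODALITIES.index(split_class(c)[0]) for c in labels])
        ints = np.array([split_class(c)[1] for c in labels])
        acc_mod = float((p_mod.argmax(1) == mods).mean())
        acc_int = float((p_int.argmax(1) == ints).mean())
        assert acc_mod > 1 / 3 + 0.1
        assert acc_int > 1 / 4 + 0.1

    def test_deterministic_given_seed(self, image_pair_problem):
        inputs, y = image_pair_problem
        spec = ArchitectureSpec(kind="cnns_fusion", epochs=2, batch_size=8,
                                image_size=16)
        a = train_cnn(spec, inputs, y, seed=9)
        b = train_cnn(spec, inputs, y, seed=9)
        np.testing.assert_array_equal(a.predict(inputs), b.predict(inputs))


class TestPredictionHelpers:
    def test_uniform_scores_tie_break_to_first_class(self):
        scores = np.full((3, 7), 1 / 7)
        assert hard_labels(scores, CLASSES) == ["B", "B", "B"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hard_labels(np.ones((2, 5)), CLASSES)

    @pytest.mark.parametrize("mod,intensity,expected", [
        ("E", 2, "E2"),
        ("H", 3, "H3"),
        ("E", 0, "B"),
        ("B", 0, "B"),
    ])
    def test_mtl_mapping(self, mod, intensity, expected):
        assert combine_mtl(mod, intensity) == expected

    def test_mtl_baseline_modality_with_pain_uses_scores(self):
        assert combine_mtl("B", 2, np.array([0.5, 0.1, 0.4])) == "E2"
        assert combine_mtl("B", 2, np.array([0.5, 0.4, 0.1])) == "H2"

    def test_mtl_scores_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = [c for c in CLASSES for _ in range(4)]
        ximg = rng.random((len(labels), 16, 16, 3))
        xpred = rng.random((len(labels), 28, 28, 1))
        for variant in ("softmax_softmax", "softmax_mse", "softmax_sigmoid"):
            spec = ArchitectureSpec(kind="cnns_fusion", mtl_variant=variant,
                                    epochs=1, batch_size=16, image_size=16)
            model = train_cnn(spec, (ximg, xpred), labels, seed=0)
            scores = model.predict((ximg, xpred))
            assert scores.shape == (len(labels), 7)
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)
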