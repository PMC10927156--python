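import numpy as np
import pytest

from ambbem.layer_classifier import (ClassifierConfig, HeuristicLayerClassifier,
                                     ImprovedResNet50Classifier, LayerClass,
                                     build_improved_resnet50, classify,
                                     evaluate_classifier, preprocess,
                                     train_classifier)
from ambbem.phantom import generate_dataset

TINY = dict(input_side=56, width=0.125)   # full topology, narrow channels


class TestPreprocess:
    def test_output_geometry_and_channel_replication(self, rng):
        img = rng.integers(0, 256, (512, 512), dtype=np.uint8)
        x = preprocess(img)
        assert x.shape == (3, 224, 224)
        assert np.array_equal(x[0], x[1]) and np.array_equal(x[0], x[2])

    def test_matching_size_is_identity_resize(self, rng):
        img = rng.integers(0, 256, (224, 224), dtype=np.uint8)
        x = preprocess(img)
        assert np.allclose(x[0], img / 255.0, atol=1e-6)

    def test_constant_white_maps_to_one(self):
        img = np.full((64, 64), 255, dtype=np.uint8)
        assert np.allclose(preprocess(img), 1.0)

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, (100, 80), dtype=np.uint8)
        assert np.array_equal(preprocess(img), preprocess(img))


class TestConfig:
    def test_published_training_defaults(self):
        cfg = ClassifierConfig()
        assert (cfg.input_side, cfg.channels, cfg.n_classes) == (224, 3, 4)
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 16
        assert cfg.epochs == 45
        assert cfg.optimizer_name == "adam"

    def test_class_count_fixed(self):
        with pytest.raises(ValueError):
            ClassifierConfig(n_classes=5)


class TestModel:
    def test_forward_is_probability_simplex(self, rng):
        model = build_improved_resnet50(ClassifierConfig(seed=1, **TINY))
        x = rng.random((2, 3, 56, 56)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (2, 4)
        assert np.all(p >= 0) and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_seeded_builds_are_identical(self, rng):
        x = rng.random((1, 3, 56, 56)).astype(np.float32)
        a = build_improved_resnet50(ClassifierConfig(seed=9, **TINY))
        b = build_improved_resnet50(ClassifierConfig(seed=9, **TINY))
        assert np.array_equal(a.forward(x), b.forward(x))

    def test_argmax_and_tie_break(self):
        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, image):
                return np.array(self.p)

        img = np.zeros((64, 64), dtype=np.uint8)
        assert classify(Fixed([0.1, 0.7, 0.1, 0.1]), img) == LayerClass.SINGLE_REGION
        assert classify(Fixed([0.25] * 4), img) == LayerClass.BASIS_CRANII


class TestTraining:
    def test_loss_decreases_on_small_set(self):
        mix = {LayerClass.BASIS_CRANII: 0.5, LayerClass.SINGLE_REGION: 0.5}
        data = [(s.image, s.layer_class)
                for s in generate_dataset(16, mix, 5, image_size=128)]
        cfg = ClassifierConfig(seed=2, epochs=3, **TINY)
        model = build_improved_resnet50(cfg)
        history = train_classifier(model, data, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_zero_epochs_is_a_no_op(self, rng):
        mix = {LayerClass.BASIS_CRANII: 0.5, LayerClass.SINGLE_REGION: 0.5}
        data = [(s.image, s.layer_class)
                for s in generate_dataset(4, mix, 5, image_size=128)]
        cfg = ClassifierConfig(seed=2, epochs=0, **TINY)
        model = build_improved_resnet50(cfg)
        x = rng.random((1, 3, 56, 56)).astype(np.float32)
        before = model.forward(x)
        history = train_classifier(model, data, cfg)
        assert history == {"loss": [], "accuracy": []}
        assert np.array_equal(model.forward(x), before)

    def test_single_class_dataset_rejected(self):
        mix = {LayerClass.SINGLE_REGION: 1.0}
        data = [(s.image, s.layer_class)
                for s in generate_dataset(4, mix, 5, image_size=128)]
        cfg = ClassifierConfig(seed=2, epochs=1, **TINY)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(build_improved_resnet50(cfg), data, cfg)


class TestEvaluate:
    def test_all_correct(self):
        class Echo:
            def __init__(self):
                self.i = 0

        data = []
        mix = {c: 0.25 for c in LayerClass}
        for s in generate_dataset(8, mix, 6, image_size=128):
            data.append((s.image, s.layer_class))
        heur = HeuristicLayerClassifier()
        acc, ap, conf = evaluate_classifier(heur, data)
        assert conf.sum() == 8
        assert 0.0 <= ap <= 1.0 and 0.0 <= acc <= 1.0

    def test_confusion_arithmetic(self):
        class Always:
            def __init__(self, cls):
                self.cls = cls

            def predict_proba(self, image):
                p = np.zeros(4)
                p[int(self.cls)] = 1.0
                return p

        mix = {LayerClass.SINGLE_REGION: 0.75, LayerClass.TWO_REGIONS: 0.25}
        data = [(s.image, s.layer_class)
                for s in generate_dataset(4, mix, 7, image_size=128)]
        acc, _, conf = evaluate_classifier(Always(LayerClass.SINGLE_REGION), data)
        assert acc == 0.75
        assert conf[int(LayerClass.SINGLE_REGION), int(LayerClass.SINGLE_REGION)] == 3


class TestHeuristic:
    def test_agreement_with_phantom_labels(self):
        """The morphology heuristic matches generator labels >= 95% on a
        seeded 100-phantom batch spanning every class and feature."""
        mix = {c: 0.25 for c in LayerClass}
        data = generate_dataset(100, mix, 17, image_size=128, gap_prob=0.3,
                                hematoma_prob=0.3, pillow_prob=0.5)
        heur = HeuristicLayerClassifier()
        agree = sum(classify(heur, s.image) == s.layer_class for s in data)
        assert agree >= 95

    def test_deterministic(self, single_region_phantom):
        heur = HeuristicLayerClassifier()
        a = classify(heur, single_region_phantom.image)
        b = classify(heur, single_region_phantom.image)
        assert a == b == LayerClass.SINGLE_REGION
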