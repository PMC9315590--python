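"""Residual classifier: architecture wiring, training recipe, inference.

Network tests run at the 16 x 16 input side with narrow stages so the
full (3, 4, 6, 3)-block architecture stays cheap on one CPU.
"""

import numpy as np
import pytest

from collateral4d import nn
from collateral4d.networks import (
    ClassProbabilities,
    MultiInputClassifier,
    NetworkConfig,
    ResidualClassifier,
    _BasicBlock,
    build_classifier,
    forward_multi,
    predict,
    train,
)
from collateral4d.synthetic import PHASE_KEYS


def tiny_config(**kw):
    defaults = dict(variant="single", input_side=16, base_width=2, seed=0)
    defaults.update(kw)
    return NetworkConfig(**defaults)


def toy_images(n, side=16, seed=0):
    """Linearly separable montages: good = bright upper-left quadrant."""
    rng = np.random.default_rng(seed)
    labels = ["good", "poor"] * (n // 2)
    images = []
    for lab in labels:
        img = rng.random((side, side), dtype=np.float32) * 0.1
        if lab == "good":
            img[: side // 2, : side // 2] += 0.8
        images.append(img)
    return np.stack(images), labels


class TestArchitecture:
    def test_blocks_per_stage(self):
        model = ResidualClassifier(tiny_config())
        blocks = [l for l in model.net.layers if isinstance(l, _BasicBlock)]
        assert len(blocks) == 16  # 3 + 4 + 6 + 3
        widths = [b.conv1.w.value.shape[0] for b in blocks]
        assert widths == [2] * 3 + [4] * 4 + [8] * 6 + [16] * 3

    def test_blocks_per_stage_is_fixed(self):
        with pytest.raises(ValueError):
            NetworkConfig(blocks_per_stage=(2, 2, 2, 2))

    def test_input_too_small_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(input_side=8)

    def test_probabilities_sum_to_one(self, rng):
        model = ResidualClassifier(tiny_config())
        p = model.predict_proba(rng.random((3, 16, 16), dtype=np.float32))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_symmetric_logits_give_half(self):
        assert np.allclose(nn.softmax(np.zeros((1, 2))), 0.5)

    def test_zero_weight_block_reduces_to_skip_path(self, rng):
        """With the residual branch zeroed the block must return its
        (non-negative) input unchanged: verifies the elementwise
        addition wiring."""
        block = _BasicBlock(4, 4, 1, np.random.default_rng(0))
        block.conv1.w.value[:] = 0
        block.conv2.w.value[:] = 0
        block.bn1.beta.value[:] = 0
        block.bn2.beta.value[:] = 0
        x = rng.random((2, 4, 8, 8)).astype(np.float32)  # non-negative input
        out = block.forward(x, train=False)
        assert np.allclose(out, x, atol=1e-6)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference check through conv, batch norm, pooling,
        a residual block and the linear head."""
        rng = np.random.default_rng(0)
        net = nn.Sequential(
            nn.Conv2d(1, 3, 3, 1, 1, rng), nn.BatchNorm2d(3), nn.ReLU(),
            nn.MaxPool2d(3, 2, 1), _BasicBlock(3, 6, 2, rng),
            nn.GlobalAvgPool(), nn.Linear(6, 2, rng),
        )
        x = rng.random((4, 1, 10, 10)).astype(np.float32)
        y = np.array([0, 1, 1, 0])
        for p in net.params():
            p.grad[...] = 0
        loss, d = nn.softmax_cross_entropy(net.forward(x, True), y)
        net.backward(d)
        check = rng
        for p in net.params():
            flat, gflat = p.value.reshape(-1), p.grad.reshape(-1)
            for i in check.choice(len(flat), size=min(4, len(flat)), replace=False):
                orig = flat[i]
                eps = 1e-3
                flat[i] = orig + eps
                lp, _ = nn.softmax_cross_entropy(net.forward(x, True), y)
                flat[i] = orig - eps
                lm, _ = nn.softmax_cross_entropy(net.forward(x, True), y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) <= 2e-2 * max(1.0, abs(num) + abs(gflat[i]))


class TestTraining:
    def test_loss_decreases_on_separable_toy_data(self):
        images, labels = toy_images(20)
        cfg = tiny_config(seed=3)
        trained = train(build_classifier(cfg), images, labels, cfg)
        assert trained.loss_history[-1] < trained.loss_history[0]

    def test_seeded_training_is_reproducible(self):
        images, labels = toy_images(8)
        cfg = tiny_config(seed=9, max_epochs=3)
        a = train(build_classifier(cfg), images, labels, cfg)
        b = train(build_classifier(cfg), images, labels, cfg)
        assert a.loss_history == b.loss_history

    def test_early_stopping_on_flat_loss(self):
        """A zero learning rate freezes the loss, so patience (2) stops
        training after 3 epochs despite max_epochs = 10."""
        images, labels = toy_images(8)
        cfg = tiny_config(seed=1, learning_rate=1e-30, max_epochs=10, patience=2)
        trained = train(build_classifier(cfg), images, labels, cfg)
        assert len(trained.loss_history) == 3

    def test_epoch_cap_at_ten(self):
        images, labels = toy_images(8)
        cfg = tiny_config(seed=1, max_epochs=50, patience=50)
        trained = train(build_classifier(cfg), images, labels, cfg)
        assert len(trained.loss_history) <= 10

    def test_single_class_rejected(self):
        images, _ = toy_images(6)
        cfg = tiny_config()
        with pytest.raises(ValueError):
            train(build_classifier(cfg), images, ["good"] * 6, cfg)


class TestInference:
    def test_predict_argmax_and_tie_rule(self):
        assert ClassProbabilities(0.9, 0.1).p_good == 0.9
        from collateral4d.networks import _decide

        assert _decide(ClassProbabilities(0.9, 0.1)) == "good"
        assert _decide(ClassProbabilities(0.1, 0.9)) == "poor"
        assert _decide(ClassProbabilities(0.5, 0.5)) == "poor"  # tie -> poor

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ClassProbabilities(0.8, 0.8)

    def test_batch_packing_invariance(self, rng):
        model = ResidualClassifier(tiny_config(seed=4))
        x = rng.random((5, 16, 16), dtype=np.float32)
        batched = model.predict_proba(x)
        singles = np.vstack([model.predict_proba(x[i]) for i in range(5)])
        assert np.allclose(batched, singles, atol=1e-6)

    def test_predict_roundtrip(self):
        images, labels = toy_images(8)
        cfg = tiny_config(seed=2, max_epochs=1)
        trained = train(build_classifier(cfg), images, labels, cfg)
        label, probs = predict(trained, images[0])
        assert label in ("good", "poor")
        assert probs.p_good + probs.p_poor == pytest.approx(1.0, abs=1e-6)


class TestMultiInput:
    def test_four_branches_same_architecture(self):
        cfg = tiny_config(variant="multi")
        model = build_classifier(cfg)
        assert isinstance(model, MultiInputClassifier)
        assert set(model.branches) == set(PHASE_KEYS)
        for b in model.branches.values():
            blocks = [l for l in b.net.layers if isinstance(l, _BasicBlock)]
            assert len(blocks) == 16

    def test_probability_averaging(self, rng):
        cfg = tiny_config(variant="multi", seed=6)
        model = build_classifier(cfg)
        images = {k: rng.random((16, 16), dtype=np.float32) for k in PHASE_KEYS}
        probs, label = forward_multi(model, images)
        manual = np.mean(
            [model.branches[k].predict_proba(images[k])[0] for k in PHASE_KEYS], axis=0
        )
        assert probs.p_poor == pytest.approx(manual[0], abs=1e-6)
        assert probs.p_good == pytest.approx(manual[1], abs=1e-6)
        assert probs.p_good + probs.p_poor == pytest.approx(1.0, abs=1e-6)

    def test_wrong_branch_count_rejected(self, rng):
        cfg = tiny_config(variant="multi")
        model = build_classifier(cfg)
        del model.branches["venous"]
        with pytest.raises(ValueError):
            forward_multi(model, {k: rng.random((16, 16)) for k in PHASE_KEYS})

    def test_multi_training_runs(self):
        images, labels = toy_images(8)
        data = {k: images for k in PHASE_KEYS}
        cfg = tiny_config(variant="multi", seed=5, max_epochs=1)
        trained = train(build_classifier(cfg), data, labels, cfg)
        assert trained.variant == "multi"
        assert len(trained.loss_history) >= 1
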