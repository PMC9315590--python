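"""Residual classifiers for collateral-circulation grading.

Two input architectures share one backbone: a 3x3 convolution stem, a
3x3 max-pooling layer, four residual stages with (3, 4, 6, 3) basic
blocks (each block two 3x3 convolutions with batch normalisation and an
elementwise skip addition), global average pooling and a two-way
fully-connected softmax head.

* single-input: the stitched 2x2 four-phase montage is classified by one
  backbone;
* multi-input: each phase MIP feeds its own backbone branch and the four
  probability vectors are averaged.

Training uses Adam (learning rate 1e-4, batch 16), cross-entropy, an
epoch cap of ten, and early stopping when the epoch-mean loss stops
decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .synthetic import PHASE_KEYS, GOOD, POOR

__all__ = [
    "NetworkConfig",
    "ClassProbabilities",
    "TrainedModel",
    "ResidualClassifier",
    "MultiInputClassifier",
    "build_classifier",
    "forward_multi",
    "train",
    "predict",
]

#: class index convention: 0 = poor, 1 = good
CLASS_ORDER = (POOR, GOOD)

RESNET34_BLOCKS = (3, 4, 6, 3)


@dataclass
class NetworkConfig:
    variant: str = "single"  # "single" | "multi"
    blocks_per_stage: tuple[int, int, int, int] = RESNET34_BLOCKS
    input_side: int = 128
    base_width: int = 8  # stage widths are (w, 2w, 4w, 8w); 64 is full scale
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 10
    patience: int = 2
    min_delta: float = 1e-4
    seed: int = 0
    pretrained: bool = False
    branch_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.variant not in ("single", "multi"):
            raise ValueError("variant must be 'single' or 'multi'")
        if tuple(self.blocks_per_stage) != RESNET34_BLOCKS:
            raise ValueError(f"blocks_per_stage is fixed to {RESNET34_BLOCKS}")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.input_side < 16:
            raise ValueError("input side too small for the downsampling chain")
        if abs(sum(self.branch_weights) - 1.0) > 1e-9:
            raise ValueError("branch weights must sum to 1")


@dataclass(frozen=True)
class ClassProbabilities:
    p_good: float
    p_poor: float

    def __post_init__(self):
        if not (0 <= self.p_good <= 1 and 0 <= self.p_poor <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_good + self.p_poor - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")


@dataclass
class TrainedModel:
    variant: str
    model: "ResidualClassifier | MultiInputClassifier"
    loss_history: list[float]
    config: NetworkConfig


class _BasicBlock(nn.Layer):
    """Two 3x3 conv+BN layers with the input added elementwise to the
    output; a strided 1x1 projection aligns the skip path when the
    spatial size or channel count changes."""

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.relu_out = nn.ReLU()
        if stride != 1 or cin != cout:
            self.proj = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride, 0, rng), nn.BatchNorm2d(cout)
            )
        else:
            self.proj = None

    def params(self):
        out = (
            self.conv1.params() + self.bn1.params()
            + self.conv2.params() + self.bn2.params()
        )
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(h + skip, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gh = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        gskip = g if self.proj is None else self.proj.backward(g)
        return gh + gskip


class ResidualClassifier:
    """Single-backbone classifier over one grayscale image."""

    def __init__(self, config: NetworkConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        w = config.base_width
        layers: list[nn.Layer] = [
            nn.Conv2d(1, w, 3, 1, 1, rng),
            nn.BatchNorm2d(w),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, 1),
        ]
        cin = w
        for stage, n_blocks in enumerate(config.blocks_per_stage):
            cout = w * (2**stage)
            for b in range(n_blocks):
                stride = 2 if (stage > 0 and b == 0) else 1
                layers.append(_BasicBlock(cin, cout, stride, rng))
                cin = cout
        layers.append(nn.GlobalAvgPool())
        # zero-initialised head: logits start at exactly (0, 0)
        layers.append(nn.Linear(cin, 2, rng, zero_init=True))
        self.net = nn.Sequential(*layers)
        if config.pretrained:
            raise NotImplementedError(
                "pretrained initialisation is an optional hook; no weights are bundled"
            )

    def params(self):
        return self.net.params()

    @staticmethod
    def _as_batch(images) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ValueError("expected (n, side, side) or (side, side) input")
        return x[:, None, :, :]  # NCHW with one channel

    def forward_logits(self, images, train=False) -> np.ndarray:
        return self.net.forward(self._as_batch(images), train)

    def predict_proba(self, images) -> np.ndarray:
        """Softmax probabilities, columns ordered (poor, good)."""
        return nn.softmax(self.forward_logits(images, train=False))


class MultiInputClassifier:
    """Four architecture-identical branches, one per phase MIP; the
    final probability vector is the (uniform by default) weighted mean
    of the branch probabilities."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        seeds = np.random.SeedSequence(config.seed).generate_state(4)
        self.branches = {
            key: ResidualClassifier(config, seed=int(s) % 2**31)
            for key, s in zip(PHASE_KEYS, seeds)
        }

    def predict_proba(self, phase_images: dict[str, np.ndarray]) -> np.ndarray:
        probs = [
            wgt * self.branches[key].predict_proba(phase_images[key])
            for key, wgt in zip(PHASE_KEYS, self.config.branch_weights)
        ]
        return np.sum(probs, axis=0)


def build_classifier(config: NetworkConfig):
    """Untrained model for the configured variant."""
    if config.variant == "single":
        return ResidualClassifier(config)
    return MultiInputClassifier(config)


def forward_multi(model: MultiInputClassifier, phase_images: dict[str, np.ndarray]):
    """Average the four branch probability vectors; returns
    (ClassProbabilities, predicted_label) for a single example."""
    if len(model.branches) != 4:
        raise ValueError("multi-input model requires exactly 4 branches")
    p = model.predict_proba({k: np.asarray(v)[None] if np.asarray(v).ndim == 2 else v
                             for k, v in phase_images.items()})[0]
    probs = ClassProbabilities(p_good=float(p[1]), p_poor=float(p[0]))
    return probs, _decide(probs)


def _decide(probs: ClassProbabilities) -> str:
    # exact tie goes to "poor": the conservative call flags the study
    # for interventional review
    return GOOD if probs.p_good > probs.p_poor else POOR


def _encode_labels(labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    try:
        y = np.array([idx[l] for l in labels])
    except KeyError as e:
        raise ValueError(f"unknown label {e.args[0]!r}") from None
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    return y


def _train_single(
    model: ResidualClassifier, images: np.ndarray, y: np.ndarray, config: NetworkConfig,
    rng: np.random.Generator,
) -> list[float]:
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    x = model._as_batch(images)
    n = len(y)
    history: list[float] = []
    best = np.inf
    stale = 0
    max_epochs = min(config.max_epochs, 10)
    for _ in range(max_epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = model.net.forward(x[sel], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[sel])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            weights.append(len(sel))
        epoch_loss = float(np.average(losses, weights=weights))
        history.append(epoch_loss)
        if epoch_loss < best - config.min_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return history


def train(model, data, labels, config: NetworkConfig | None = None) -> TrainedModel:
    """Fit a built classifier.

    single variant: ``data`` is an array/list of montage images
    (n, side, side).  multi variant: ``data`` is a dict phase ->
    (n, side, side) of per-phase MIPs; each branch is trained
    independently on its phase and the ensemble averages at inference.
    """
    config = config or model.config
    y = _encode_labels(labels)
    rng = np.random.default_rng(config.seed)
    if isinstance(model, ResidualClassifier):
        images = np.asarray(data, dtype=np.float32)
        history = _train_single(model, images, y, config, rng)
    elif isinstance(model, MultiInputClassifier):
        per_branch = []
        for key in PHASE_KEYS:
            branch_rng = np.random.default_rng(rng.integers(2**31))
            imgs = np.asarray(data[key], dtype=np.float32)
            per_branch.append(
                _train_single(model.branches[key], imgs, y, config, branch_rng)
            )
        depth = max(len(h) for h in per_branch)
        history = [
            float(np.mean([h[min(e, len(h) - 1)] for h in per_branch]))
            for e in range(depth)
        ]
    else:
        raise TypeError("model must be a built single- or multi-input classifier")
    return TrainedModel(
        variant=config.variant, model=model, loss_history=history, config=config
    )


def predict(trained: TrainedModel, x) -> tuple[str, ClassProbabilities]:
    """Class with the larger probability; exact ties go to poor."""
    model = trained.model
    if isinstance(model, MultiInputClassifier):
        return forward_multi(model, x)[::-1]
    p = model.predict_proba(np.asarray(x))
    if p.shape[0] != 1:
        raise ValueError("predict takes one example; use predict_proba for batches")
    probs = ClassProbabilities(p_good=float(p[0, 1]), p_poor=float(p[0, 0]))
    return _decide(probs), probs
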