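"""Pixel-wise nodule segmentation network: build, train, update, predict.

A U-Net-style encoder-decoder maps an RGB root image at the fixed network
size to a per-pixel foreground probability.  The same model object
supports initial training on a manually annotated set and incremental
updates with additional (corrected) training pairs — the
transfer-learning half of the semi-automatic annotation loop.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from ._nn import F32, Adam, UNet, dice_bce_loss, sigmoid

__all__ = [
    "SegModelConfig",
    "TrainHistory",
    "SegModel",
    "build_model",
    "train",
    "update",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SegModelConfig:
    """Network and optimization settings.

    The defaults are a desk-scale configuration (128-pixel inputs, three
    resolution levels, 16 base channels) that trains on a CPU in minutes;
    the full-resolution setup (1024-pixel inputs, deeper network) is the
    same code with different numbers.
    """

    input_size: int = 128
    depth: int = 3
    base_channels: int = 16
    seed: int = 0
    loss: str = "dice_bce"
    learning_rate: float = 3e-3
    batch_size: int = 4
    epochs: int = 30

    def validate(self) -> None:
        if self.input_size <= 0 or self.input_size % 32 != 0:
            raise ValueError("input_size must be a positive multiple of 32")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}"
            )
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss != "dice_bce":
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainHistory:
    """Per-epoch record of one training run."""

    losses: list[float] = field(default_factory=list)
    val_f1: list[float] | None = None
    n_training_pairs: int = 0


@dataclass
class SegModel:
    """A segmentation model handle: network, config, and replay memory."""

    net: UNet
    config: SegModelConfig
    trained: bool = False
    train_pairs: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def build_model(config: SegModelConfig) -> SegModel:
    """Construct a model with deterministic (seeded) initialization."""
    config.validate()
    net = UNet(config.input_size, config.depth, config.base_channels, config.seed)
    return SegModel(net=net, config=config)


def _as_input(image: np.ndarray, input_size: int) -> np.ndarray:
    """Validate and normalize one RGB image to float32 (3, S, S) in [0, 1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.shape[0] != input_size or image.shape[1] != input_size:
        raise ValueError(
            f"image dims {image.shape[:2]} do not match network input size {input_size}"
        )
    x = image.astype(F32)
    if image.dtype == np.uint8 or x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x)


def _as_target(mask: np.ndarray, input_size: int) -> np.ndarray:
    if mask.shape[:2] != (input_size, input_size):
        raise ValueError(
            f"mask dims {mask.shape[:2]} do not match network input size {input_size}"
        )
    return (np.asarray(mask) > 0).astype(F32)[:, :, None]


def _pixel_f1(prob: np.ndarray, truth: np.ndarray) -> float:
    pred = prob >= 0.5
    t = truth > 0
    tp = float(np.logical_and(pred, t).sum())
    fp = float(np.logical_and(pred, ~t).sum())
    fn = float(np.logical_and(~pred, t).sum())
    if tp == 0.0:
        return 1.0 if fp == 0.0 and fn == 0.0 else 0.0
    return 2 * tp / (2 * tp + fp + fn)


def _run_training(
    model: SegModel,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: SegModelConfig,
    val_pairs: list[tuple[np.ndarray, np.ndarray]] | None,
    rng_seed: int,
) -> TrainHistory:
    size = config.input_size
    xs = np.stack([_as_input(img, size) for img, _ in pairs])
    ys = np.stack([_as_target(m, size) for _, m in pairs])
    n = len(pairs)
    rng = np.random.default_rng(rng_seed)
    opt = Adam(model.net, lr=config.learning_rate)
    history = TrainHistory(n_training_pairs=n, val_f1=[] if val_pairs is not None else None)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = xs[idx], ys[idx]
            model.net.zero_grad()
            logits = model.net.forward(xb, train=True)
            loss, dlogits = dice_bce_loss(logits, yb)
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        history.losses.append(epoch_loss / n)
        if val_pairs is not None:
            f1s = [
                _pixel_f1(predict(model, img), msk) for img, msk in val_pairs
            ]
            history.val_f1.append(float(np.mean(f1s)))
    return history


def train(
    model: SegModel,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: SegModelConfig | None = None,
    *,
    val_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[SegModel, TrainHistory]:
    """Train from the current (usually fresh) parameters on ``pairs``.

    ``pairs`` is a list of ``(rgb_image, binary_mask)`` at the network
    input size.  The pairs are retained on the model as replay memory for
    later :func:`update` calls.
    """
    if not pairs:
        raise ValueError("training set is empty")
    config = config or model.config
    config.validate()
    history = _run_training(model, pairs, config, val_pairs, rng_seed=config.seed + 1)
    model.trained = True
    model.train_pairs = list(pairs)
    return model, history


def update(
    model: SegModel,
    additional_pairs: list[tuple[np.ndarray, np.ndarray]],
    config: SegModelConfig | None = None,
    *,
    val_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[SegModel, TrainHistory]:
    """Continue optimization with additional (e.g. corrected) pairs.

    Optimization resumes from the current parameters on the union of the
    remembered training pairs and the new ones (replay), so earlier
    knowledge is not forgotten; if no replay memory exists (a loaded
    checkpoint), only the new pairs are used.
    """
    if not model.trained:
        raise ValueError("update() requires a previously trained model")
    if not additional_pairs:
        raise ValueError("additional training set is empty")
    config = config or model.config
    config.validate()
    pairs = list(model.train_pairs) + list(additional_pairs)
    history = _run_training(
        model, pairs, config, val_pairs, rng_seed=config.seed + 1 + len(pairs)
    )
    model.train_pairs = pairs
    return model, history


def predict(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel foreground probability map for one image at input size."""
    x = _as_input(image, model.config.input_size)[None]
    logits = model.net.forward(x, train=False)
    return sigmoid(logits)[0, :, :, 0].astype(np.float64)


def save_model(model: SegModel, path: str | Path) -> None:
    """Save parameters + config to a single ``.npz`` checkpoint file."""
    state = model.net.state_dict()
    np.savez_compressed(
        path,
        _config=json.dumps(asdict(model.config)),
        _trained=np.array(int(model.trained)),
        **state,
    )


def load_model(path: str | Path) -> SegModel:
    with np.load(path, allow_pickle=False) as data:
        config = SegModelConfig(**json.loads(str(data["_config"])))
        model = build_model(config)
        model.net.load_state_dict({k: data[k] for k in data.files if k.startswith("conv")})
        model.trained = bool(int(data["_trained"]))
    return model
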