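"""Encoder–decoder (U-Net) artifact-reduction network and training harness.

Architecture contract: each contraction level applies two 3×3 convolutions,
each followed by ReLU and batch normalization, then 2×2 max pooling with
stride 2; the first level produces ``base_channels`` (64 by default) feature
maps and the count doubles per level. The expansion path mirrors this with
stride-2 transposed-convolution upsampling that halves the channel count,
concatenation skip connections from the matching contraction level, and two
convolutions per level; a final 1×1 convolution produces the output image.
Training minimizes the L2 (mean squared error) loss with Adam, learning
rate 0.0005 for 300 epochs by default.

Two dataset modes are supported. In ``direct`` mode the network maps the
corrupted image to the clean image. In ``residual`` mode it maps the
corrupted image to the signed residual map (artifact − clean), and the
corrected image is the artifact minus the predicted residual — the residual
carries only artifact information, which is an easier regression target.

The reference-scale configuration (depth 4, base 64, 300 epochs, 256×256
inputs) is expressible but heavyweight; the harness is routinely run at
desk scale (smaller depth/base/epochs) for experimentation and testing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from .dataset import DatasetSplit, PairedSample

__all__ = ["ModelConfig", "TrainedModel", "build_model", "train",
           "correct_image", "save_model", "load_model"]


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    base_channels: int = 64
    learning_rate: float = 5e-4
    epochs: int = 300
    batch_size: int = 4
    loss: str = "l2"
    mode: str = "direct"  # "direct" | "residual"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")
        if self.mode not in ("direct", "residual"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.loss != "l2":
            raise ValueError("only the L2 (mean squared error) loss is supported")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.depth))


class UNet:
    """The network graph; parameters are float32 NumPy arrays."""

    def __init__(self, cfg: ModelConfig, in_channels: int = 1):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.enc_blocks: list[_nn.Sequential] = []
        self.pools: list[_nn.MaxPool2] = []
        self.ups: list[_nn.ConvTranspose2] = []
        self.dec_blocks: list[_nn.Sequential] = []

        def conv_block(c_in, c_out):
            return _nn.Sequential([
                _nn.Conv2d(c_in, c_out, 3, rng), _nn.ReLU(), _nn.BatchNorm2d(c_out),
                _nn.Conv2d(c_out, c_out, 3, rng), _nn.ReLU(), _nn.BatchNorm2d(c_out),
            ])

        c_prev = in_channels
        for c in cfg.encoder_channels:
            self.enc_blocks.append(conv_block(c_prev, c))
            self.pools.append(_nn.MaxPool2())
            c_prev = c
        c_bottom = cfg.base_channels * 2**cfg.depth
        self.bottleneck = conv_block(c_prev, c_bottom)
        c_prev = c_bottom
        for c in reversed(cfg.encoder_channels):
            self.ups.append(_nn.ConvTranspose2(c_prev, c, rng))
            self.dec_blocks.append(conv_block(2 * c, c))
            c_prev = c
        self.head = _nn.Conv2d(c_prev, 1, 1, rng)

    def params(self) -> list[_nn.Param]:
        out = []
        for blk in self.enc_blocks:
            out += blk.params()
        out += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec_blocks):
            out += up.params() + blk.params()
        out += self.head.params()
        return out

    def _check_input(self, x: np.ndarray) -> None:
        side = 2**self.cfg.depth
        if x.shape[2] % side or x.shape[3] % side:
            raise ValueError(
                f"input sides {x.shape[2]}x{x.shape[3]} must be divisible by "
                f"2^depth = {side}"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._check_input(x)
        skips = []
        h = np.asarray(x, dtype=_nn.DTYPE)
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, training)
            self._skip_channels.append(skip.shape[1])
            h = blk.forward(_nn.concat_channels(skip, h), training)
        return self.head.forward(h, training)

    def backward(self, dy: np.ndarray) -> None:
        dh = self.head.backward(dy)
        dskips = []
        for blk, up, c_skip in zip(reversed(self.dec_blocks), reversed(self.ups),
                                   reversed(self._skip_channels)):
            dcat = blk.backward(dh)
            dskip, dh = _nn.split_channels(dcat, c_skip)
            dskips.append(dskip)
            dh = up.backward(dh)
        dh = self.bottleneck.backward(dh)
        # dskips was collected shallowest-first; the encoder walks deepest-first
        for blk, pool, dskip in zip(reversed(self.enc_blocks), reversed(self.pools),
                                    reversed(dskips)):
            dh = pool.backward(dh)
            dh = dh + dskip
            dh = blk.backward(dh)


@dataclass
class TrainedModel:
    net: UNet
    config: ModelConfig
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"train": [], "validation": []})

    @property
    def is_trained(self) -> bool:
        return len(self.history["train"]) > 0


def build_model(cfg: ModelConfig) -> TrainedModel:
    """Construct an untrained network; identical seeds give identical weights."""
    return TrainedModel(net=UNet(cfg), config=cfg)


def _tensors(samples: list[PairedSample], indices: list[int],
             mode: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([samples[i].artifact for i in indices])[:, None].astype(_nn.DTYPE)
    if mode == "residual":
        y = np.stack([samples[i].residual for i in indices])[:, None].astype(_nn.DTYPE)
    else:
        y = np.stack([samples[i].clean for i in indices])[:, None].astype(_nn.DTYPE)
    return x, y


def train(model: TrainedModel, samples: list[PairedSample], split: DatasetSplit,
          cfg: ModelConfig | None = None, verbose: bool = False) -> TrainedModel:
    """Minimize the L2 loss with Adam over the training partition.

    Inputs are artifact slices; targets are clean slices (direct mode) or
    residual maps (residual mode). Records per-epoch mean training loss and,
    when a validation partition exists, validation loss. ``epochs=0``
    returns the model unchanged with an empty history.
    """
    cfg = cfg or model.config
    if not split.train:
        raise ValueError("empty training partition")
    x_train, y_train = _tensors(samples, split.train, cfg.mode)
    has_val = len(split.validation) > 0
    if has_val:
        x_val, y_val = _tensors(samples, split.validation, cfg.mode)

    opt = _nn.Adam(model.net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(x_train)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            pred = model.net.forward(x_train[idx], training=True)
            loss, dpred = _nn.mse_loss(pred, y_train[idx])
            opt.zero_grad()
            model.net.backward(dpred)
            opt.step()
            losses.append(loss)
        model.history["train"].append(float(np.mean(losses)))
        if has_val:
            pred = model.net.forward(x_val, training=False)
            val_loss = float(np.mean((pred - y_val) ** 2))
            model.history["validation"].append(val_loss)
        if verbose:
            msg = f"epoch {epoch + 1}/{cfg.epochs} train={model.history['train'][-1]:.6f}"
            if has_val:
                msg += f" val={model.history['validation'][-1]:.6f}"
            print(msg)
    return model


def predict(model: TrainedModel, artifact: np.ndarray) -> np.ndarray:
    """Raw network output for one 2D artifact slice."""
    x = np.asarray(artifact, dtype=_nn.DTYPE)[None, None]
    return model.net.forward(x, training=False)[0, 0]


def correct_image(model: TrainedModel, artifact: np.ndarray) -> np.ndarray:
    """Corrected image for one artifact slice, clipped to nonnegative values.

    Direct mode: the network output is the corrected image. Residual mode:
    corrected = artifact − predicted residual (residual = artifact − clean,
    so subtracting the prediction recovers the clean image).
    """
    artifact = np.asarray(artifact)
    if artifact.ndim != 2:
        raise ValueError("correct_image expects a single 2D slice")
    out = predict(model, artifact)
    if model.config.mode == "residual":
        out = artifact - out
    return np.clip(out, 0.0, None)


def save_model(model: TrainedModel, directory: str) -> None:
    """Weights as .npz plus a JSON config/history sidecar."""
    os.makedirs(directory, exist_ok=True)
    arrays = {f"p{i}": p.value for i, p in enumerate(model.net.params())}
    bn = [layer for layer in _iter_layers(model.net) if isinstance(layer, _nn.BatchNorm2d)]
    for i, layer in enumerate(bn):
        arrays[f"bn{i}_mean"] = layer.running_mean
        arrays[f"bn{i}_var"] = layer.running_var
    np.savez(os.path.join(directory, "weights.npz"), **arrays)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump({"config": asdict(model.config), "history": model.history}, fh)


def load_model(directory: str) -> TrainedModel:
    with open(os.path.join(directory, "config.json")) as fh:
        meta = json.load(fh)
    model = build_model(ModelConfig(**meta["config"]))
    model.history = meta["history"]
    data = np.load(os.path.join(directory, "weights.npz"))
    for i, p in enumerate(model.net.params()):
        p.value[...] = data[f"p{i}"]
    bn = [layer for layer in _iter_layers(model.net) if isinstance(layer, _nn.BatchNorm2d)]
    for i, layer in enumerate(bn):
        layer.running_mean = data[f"bn{i}_mean"]
        layer.running_var = data[f"bn{i}_var"]
    return model


def _iter_layers(net: UNet):
    for blk in net.enc_blocks:
        yield from blk.layers
    yield from net.bottleneck.layers
    for up, blk in zip(net.ups, net.dec_blocks):
        yield up
        yield from blk.layers
    yield net.head
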