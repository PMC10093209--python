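"""Convolutional U-net cancer score over rasterised cell features.

Pixel-wise regression of the tumour/non-tumour label from the 10-channel
cell-feature raster.  Architecture: 3x3 stride-1 convolutions with 16
feature maps at the highest resolution, three down-sampling steps by 4x4
stride-2 convolutions that double the feature maps, LeakyReLU (slope 0.2)
after every convolution, and a mirrored decoder (nearest up-sampling + 3x3
convolution with skip concatenation; the decoder design is not pinned down
by the encoder description, so a standard U-net mirror is used).  Trained
with MSE loss and Adam on random square patches (256 px at full study scale,
batch 2), keeping the checkpoint with minimum validation loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, Conv2d, Layer, ReLU, Sequential, UpsampleNearest, get_state, mse_loss, set_state


@dataclass
class UNetConfig:
    in_channels: int = 10
    base_maps: int = 16
    n_levels: int = 3  # number of down-sampling steps
    leaky_slope: float = 0.2
    learning_rate: float = 1e-3
    patch_px: int = 256
    batch_size: int = 2
    epochs: int = 5000
    val_interval: int = 10
    #: divide each input channel by its 99th percentile over the training
    #: slides (fitted once, stored with the model).  The cell features are
    #: fed raw — no per-feature distribution shaping — but their scales span
    #: orders of magnitude, and a fixed per-channel scale keeps short Adam
    #: schedules well-conditioned.
    input_scaling: bool = True

    @classmethod
    def desk_scale(cls, **overrides) -> "UNetConfig":
        """Reduced preset for CPU-scale experiments (small slides, 200 epochs)."""
        kw = dict(patch_px=128, epochs=200)
        kw.update(overrides)
        return cls(**kw)


class UNet(Layer):
    """Encoder-decoder with skip connections; input (N, C, H, W), output (N, 1, H, W)."""

    def __init__(self, rng: np.random.Generator, config: UNetConfig):
        super().__init__()
        c = config.base_maps
        slope = config.leaky_slope
        self.n_levels = config.n_levels

        def block(c_in, c_out):
            return Sequential(Conv2d(rng, c_in, c_out, 3), ReLU(slope))

        self.enc = []
        c_in = config.in_channels
        maps = [c * (2**k) for k in range(config.n_levels + 1)]
        for k in range(config.n_levels + 1):
            layers = []
            if k > 0:  # down-sampling: 4x4 conv, stride 2
                layers += [Conv2d(rng, maps[k - 1], maps[k], 4, stride=2, pad=1), ReLU(slope)]
            layers += [block(c_in if k == 0 else maps[k], maps[k]), block(maps[k], maps[k])]
            self.enc.append(Sequential(*layers))
        self.up = []
        self.dec = []
        for k in range(config.n_levels, 0, -1):
            self.up.append(Sequential(UpsampleNearest(2), block(maps[k], maps[k - 1])))
            self.dec.append(block(2 * maps[k - 1], maps[k - 1]))
        self.head = Conv2d(rng, maps[0], 1, 1, pad=0)
        # zero-init the regression head: raw cell features are O(10^2-10^3),
        # so a random head would start with huge MSE and waste most of a short
        # training budget scaling itself down
        self.head.W[...] = 0.0

        for mod in [*self.enc, *self.up, *self.dec, self.head]:
            self.params.extend(mod.params)
            self.grads.extend(mod.grads)

    def forward(self, x, train=True):
        skips = []
        for k, enc in enumerate(self.enc):
            x = enc.forward(x, train)
            if k < self.n_levels:
                skips.append(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._split = skip.shape[1]
            x = dec.forward(np.concatenate([skip, x], axis=1), train)
        return self.head.forward(x, train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        skip_grads = []
        # decoder backward in reverse order of forward
        for up, dec in zip(self.up[::-1], self.dec[::-1]):
            g = dec.backward(grad)
            c_skip = dec.layers[0].W.shape[1] // 2
            skip_grads.append(g[:, :c_skip])
            grad = up.backward(g[:, c_skip:])
        # encoder backward, adding skip gradients
        for k in range(self.n_levels, -1, -1):
            if k < self.n_levels:
                # skip_grads[i] was produced by the decoder stage that consumed
                # skips[i] (shallowest decoder first), so it indexes by level
                grad = grad + skip_grads[k]
            grad = self.enc[k].backward(grad)
        return grad


@dataclass
class UNetModel:
    net: UNet
    config: UNetConfig
    channel_scale: np.ndarray | None = None
    best_val_loss: float = np.inf
    history: list[tuple[int, float]] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "kind": "unet",
            "in_channels": self.config.in_channels,
            "base_maps": self.config.base_maps,
            "n_levels": self.config.n_levels,
            "best_val_loss": float(self.best_val_loss),
        }


def _pad_to(raster: np.ndarray, size: int) -> np.ndarray:
    """Reflect-pad the spatial dims up to at least ``size`` and to a multiple of 8."""
    h, w = raster.shape[-2:]
    th = max(size, int(np.ceil(h / 8)) * 8)
    tw = max(size, int(np.ceil(w / 8)) * 8)
    if th == h and tw == w:
        return raster
    pad = [(0, 0)] * (raster.ndim - 2) + [(0, th - h), (0, tw - w)]
    return np.pad(raster, pad, mode="reflect")


def _random_patch(
    raster: np.ndarray, mask: np.ndarray, patch: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    _, h, w = raster.shape
    y = int(rng.integers(0, h - patch + 1))
    x = int(rng.integers(0, w - patch + 1))
    return raster[:, y : y + patch, x : x + patch], mask[y : y + patch, x : x + patch]


def train_unet(
    train_slides: list[tuple[np.ndarray, np.ndarray]],
    val_slides: list[tuple[np.ndarray, np.ndarray]],
    config: UNetConfig | None = None,
    seed: int = 0,
) -> UNetModel:
    """Train the U-net on (raster, mask) slides, checkpointing on validation loss.

    Each epoch draws one random patch per training slide (so potentially a
    different crop every iteration) and steps Adam on mini-batches of
    ``batch_size`` patches.  Every ``val_interval`` epochs the loss over the
    validation slides (central patch) is evaluated and the best parameter
    state kept; that state is restored before returning.  Slides smaller
    than the patch are reflect-padded with a warning.
    """
    config = config or UNetConfig()
    if not train_slides or not val_slides:
        raise ValueError("training and validation slides are both required")
    rng = np.random.default_rng(seed)
    net = UNet(rng, config)
    opt = Adam(net.params, net.grads, lr=config.learning_rate)

    def prep(raster, mask):
        raster = np.asarray(raster, dtype=np.float32)
        mask = np.asarray(mask, dtype=np.float32)
        if raster.ndim != 3 or raster.shape[0] != config.in_channels:
            raise ValueError(
                f"expected a ({config.in_channels}, h, w) raster, got shape {raster.shape}"
            )
        if raster.shape[-2] < config.patch_px or raster.shape[-1] < config.patch_px:
            warnings.warn("slide smaller than the training patch; reflect-padded")
        return _pad_to(raster, config.patch_px), _pad_to(mask, config.patch_px)

    train_data = [prep(r, m) for r, m in train_slides]
    val_data = [prep(r, m) for r, m in val_slides]

    scale = None
    if config.input_scaling:
        stacked = np.concatenate([r.reshape(config.in_channels, -1) for r, _ in train_data], axis=1)
        scale = np.maximum(np.percentile(stacked, 99.0, axis=1), 1e-6).astype(np.float32)
        train_data = [(r / scale[:, None, None], m) for r, m in train_data]
        val_data = [(r / scale[:, None, None], m) for r, m in val_data]

    model = UNetModel(net, config, channel_scale=scale)
    best_state = get_state(net)

    def val_loss() -> float:
        total = 0.0
        for raster, mask in val_data:
            x = raster[None, :, : config.patch_px, : config.patch_px]
            y = mask[None, None, : config.patch_px, : config.patch_px]
            loss, _ = mse_loss(net.forward(x, train=False), y)
            total += loss
        return total / len(val_data)

    for epoch in range(1, config.epochs + 1):
        patches = [_random_patch(r, m, config.patch_px, rng) for r, m in train_data]
        rng.shuffle(patches)
        for start in range(0, len(patches), config.batch_size):
            chunk = patches[start : start + config.batch_size]
            x = np.stack([p[0] for p in chunk])
            y = np.stack([p[1] for p in chunk])[:, None]
            pred = net.forward(x, train=True)
            _, grad = mse_loss(pred, y)
            net.backward(grad.astype(np.float32))
            opt.step()
        if epoch % config.val_interval == 0 or epoch == config.epochs:
            loss = val_loss()
            model.history.append((epoch, loss))
            if loss < model.best_val_loss:
                model.best_val_loss = loss
                best_state = get_state(net)
    set_state(net, best_state)
    return model


@dataclass
class ScoreMap:
    """Cancer-score raster in [0, 1] aligned to slide coordinates."""

    values: np.ndarray  # (h, w) float32
    slide_id: str = "slide"
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("score map values must lie in [0, 1]")


def predict_unet(
    model: UNetModel, raster: np.ndarray, slide_id: str = "slide", stride: int | None = None
) -> ScoreMap:
    """Tile the full raster with overlapping patches, average the seams,
    clip to [0, 1]."""
    raster = np.asarray(raster, dtype=np.float32)
    if raster.shape[0] != model.config.in_channels:
        raise ValueError(
            f"expected {model.config.in_channels} channels, got {raster.shape[0]}"
        )
    if model.channel_scale is not None:
        raster = raster / model.channel_scale[:, None, None]
    h, w = raster.shape[1:]
    patch = model.config.patch_px
    padded = _pad_to(raster, patch)
    ph, pw = padded.shape[1:]
    stride = stride or patch // 2
    acc = np.zeros((ph, pw), dtype=np.float64)
    weight = np.zeros((ph, pw), dtype=np.float64)
    ys = sorted({min(y, ph - patch) for y in range(0, ph, stride)})
    xs = sorted({min(x, pw - patch) for x in range(0, pw, stride)})
    for y in ys:
        for x in xs:
            out = model.net.forward(padded[None, :, y : y + patch, x : x + patch], train=False)
            acc[y : y + patch, x : x + patch] += out[0, 0]
            weight[y : y + patch, x : x + patch] += 1.0
    values = np.clip(acc / np.maximum(weight, 1.0), 0.0, 1.0)[:h, :w].astype(np.float32)
    score = ScoreMap(values, slide_id, provenance=model.manifest())
    score.validate()
    return score
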