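"""Modified U-Net for vein segmentation.

Encoder--decoder with skip connections: four contracting blocks of two 3x3
convolutions + ReLU followed by 2x2 max pooling, starting at 16 filters and
doubling per block up to 128; a two-convolution bottleneck; four expansive
blocks of a stride-2 3x3 transposed convolution, skip concatenation, dropout
(10%) and a single 3x3 convolution + ReLU (the dropout replaces the second
convolution of the classic design); a final 1x1 convolution with sigmoid
output.  The first contracting convolution is initialised with Gabor kernels
(oriented band-pass filters matched to ridge-like vessels) that remain
trainable.  There are no fully connected layers, so the trainable parameter
count is independent of the input resolution.

Training uses the Dice coefficient as the loss (1 - Dice on the soft
prediction), the Adam optimiser, a reduce-on-plateau learning-rate schedule
and optional early stopping on the validation Dice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import metrics
from .nn import (Adam, Conv2D, Dropout, MaxPool2D, ReLU, Sigmoid, Upsample2x)
from .training import PlateauScheduler, TrainingReport

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaborParams:
    enabled: bool = True
    wavelength: float = 4.0   # px
    n_orientations: int = 4
    sigma: float = 2.0


@dataclass(frozen=True)
class UNetConfig:
    input_size: tuple = (256, 256)
    base_filters: int = 16
    depth: int = 4
    bottleneck_filters: int = 256
    dropout_rate: float = 0.10
    gabor: GaborParams = field(default_factory=GaborParams)
    lr0: float = 0.0015
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    early_stop_patience: int = 15
    epochs: int = 100
    batch_size: int = 16
    split: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        h, w = self.input_size
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(f"input dims must be divisible by 2^{self.depth}")


def gabor_bank(n_kernels: int, params: GaborParams, k: int = 3) -> np.ndarray:
    """(n_kernels, k, k) bank of oriented Gabor kernels (zero-mean, unit L2)."""
    half = (k - 1) / 2.0
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    out = np.empty((n_kernels, k, k), dtype=np.float32)
    for i in range(n_kernels):
        theta = np.pi * (i % params.n_orientations) / params.n_orientations
        lam = params.wavelength * (1.0 + 0.25 * (i // params.n_orientations))
        xr = xs * np.cos(theta) + ys * np.sin(theta)
        yr = -xs * np.sin(theta) + ys * np.cos(theta)
        g = np.exp(-(xr ** 2 + yr ** 2) / (2 * params.sigma ** 2)) * np.cos(2 * np.pi * xr / lam)
        g -= g.mean()
        norm = np.linalg.norm(g)
        out[i] = (g / norm if norm > 0 else g).astype(np.float32)
    return out


class UNet:
    """The segmentation network; input and output are (N, 1, H, W)."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0E75]))
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD80]))
        f = [cfg.base_filters * 2 ** i for i in range(cfg.depth)]     # 16,32,64,128

        self.enc = []
        c_in = 1
        for i, c in enumerate(f):
            block = {
                "conv1": Conv2D(c_in, c, 3, rng=rng, name=f"enc{i}.conv1"),
                "relu1": ReLU(),
                "conv2": Conv2D(c, c, 3, rng=rng, name=f"enc{i}.conv2"),
                "relu2": ReLU(),
                "pool": MaxPool2D(),
            }
            self.enc.append(block)
            c_in = c

        cb = cfg.bottleneck_filters
        self.bott = {
            "conv1": Conv2D(f[-1], cb, 3, rng=rng, name="bott.conv1"),
            "relu1": ReLU(),
            "conv2": Conv2D(cb, cb, 3, rng=rng, name="bott.conv2"),
            "relu2": ReLU(),
        }

        self.dec = []
        c_in = cb
        for i, c in enumerate(reversed(f)):                           # 128,64,32,16
            block = {
                "up": Upsample2x(),
                "upconv": Conv2D(c_in, c, 3, rng=rng, name=f"dec{i}.upconv"),
                "drop": Dropout(cfg.dropout_rate, self._dropout_rng),
                "conv": Conv2D(2 * c, c, 3, rng=rng, name=f"dec{i}.conv"),
                "relu": ReLU(),
            }
            self.dec.append(block)
            c_in = c

        self.head = Conv2D(f[0], 1, 1, rng=rng, name="head")
        self.sigmoid = Sigmoid()

        if cfg.gabor.enabled:
            bank = gabor_bank(f[0], cfg.gabor)
            scale = float(np.abs(self.enc[0]["conv1"].W.value).mean()) * 3.0
            self.enc[0]["conv1"].W.value[:, 0, :, :] = bank * scale

        log.info("U-Net built: %d trainable parameters across %d weighted layers "
                 "(input %s)", self.n_params(), len(self.params()) // 2, cfg.input_size)

    # -- graph traversal ---------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        skips = []
        for b in self.enc:
            x = b["relu1"].forward(b["conv1"].forward(x, train), train)
            x = b["relu2"].forward(b["conv2"].forward(x, train), train)
            skips.append(x)
            x = b["pool"].forward(x, train)
        x = self.bott["relu1"].forward(self.bott["conv1"].forward(x, train), train)
        x = self.bott["relu2"].forward(self.bott["conv2"].forward(x, train), train)
        for b, skip in zip(self.dec, reversed(skips)):
            x = b["upconv"].forward(b["up"].forward(x, train), train)
            x = np.concatenate([x, skip], axis=1)
            x = b["drop"].forward(x, train)
            x = b["relu"].forward(b["conv"].forward(x, train), train)
        return self.sigmoid.forward(self.head.forward(x, train), train)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(self.sigmoid.backward(grad))
        skip_grads = []
        for b in reversed(self.dec):
            g = b["conv"].backward(b["relu"].backward(g))
            g = b["drop"].backward(g)
            c = g.shape[1] // 2
            skip_grads.append(g[:, c:])
            g = b["up"].backward(b["upconv"].backward(np.ascontiguousarray(g[:, :c])))
        g = self.bott["conv2"].backward(self.bott["relu2"].backward(g))
        g = self.bott["conv1"].backward(self.bott["relu1"].backward(g))
        # skip_grads were collected from the deepest decoder block backwards,
        # i.e. in the order of skips[0..]; reverse to pair with reversed(enc)
        for b, sg in zip(reversed(self.enc), skip_grads[::-1]):
            g = b["pool"].backward(g) + sg
            g = b["conv2"].backward(b["relu2"].backward(g))
            g = b["conv1"].backward(b["relu1"].backward(g))

    def params(self):
        out = []
        for b in self.enc:
            out += b["conv1"].params() + b["conv2"].params()
        out += self.bott["conv1"].params() + self.bott["conv2"].params()
        for b in self.dec:
            out += b["upconv"].params() + b["conv"].params()
        out += self.head.params()
        return out

    def bn_stats(self):
        return []

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def config_dict(self) -> dict:
        d = asdict(self.cfg)
        d["model"] = "unet"
        return d


def build_unet(cfg: UNetConfig | None = None) -> UNet:
    return UNet(cfg or UNetConfig())


# The Dice coefficient / loss on arrays are shared with the metrics module.
dice_coefficient = metrics.dice_coefficient
dice_loss = metrics.dice_loss


def _soft_dice_batch(p: np.ndarray, y: np.ndarray, smooth: float = 1e-6):
    """Mean per-sample soft Dice loss and its gradient w.r.t. p.

    p, y: (N, 1, H, W); gradient of mean(1 - dice_i).
    """
    n = p.shape[0]
    axes = (1, 2, 3)
    inter = (p * y).sum(axis=axes)
    sp = p.sum(axis=axes)
    sy = y.sum(axis=axes)
    denom = sp + sy + smooth
    dice = (2 * inter + smooth) / denom
    loss = float(np.mean(1.0 - dice))
    # d dice_i / d p = (2 y * denom - (2 inter + smooth)) / denom^2
    grad = -(2 * y * denom.reshape(-1, 1, 1, 1)
             - (2 * inter + smooth).reshape(-1, 1, 1, 1)) / (denom ** 2).reshape(-1, 1, 1, 1)
    return loss, (grad / n).astype(np.float32)


def _as_batches(idx: np.ndarray, batch_size: int):
    for i in range(0, len(idx), batch_size):
        yield idx[i:i + batch_size]


def subject_split(groups, split: float, seed: int):
    """Deterministic split by subject so both sessions of a wrist stay on one
    side; returns (train_indices, val_indices)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x59117]))
    perm = rng.permutation(len(uniq))
    n_train = max(1, int(round(split * len(uniq))))
    if n_train >= len(uniq) and split < 1.0:
        n_train = len(uniq) - 1
    train_g = set(uniq[perm[:n_train]])
    train_idx = np.flatnonzero([g in train_g for g in groups])
    val_idx = np.flatnonzero([g not in train_g for g in groups])
    return train_idx, val_idx


def train_unet(model: UNet, images, masks, cfg: UNetConfig | None = None,
               groups=None) -> TrainingReport:
    """Train on (images, masks); images uint8 or float, masks binary {0,1}.

    ``groups`` (e.g. subject ids) drive the deterministic 80:20 train/val
    split; without groups each image is its own group.
    """
    cfg = cfg or model.cfg
    images = np.asarray(images)
    masks = np.asarray(masks)
    if images.size == 0:
        raise ValueError("empty dataset")
    x = (images.astype(np.float32) / 255.0 if images.dtype == np.uint8
         else images.astype(np.float32))[:, None, :, :]
    y = (masks > 0.5).astype(np.float32)[:, None, :, :]
    if groups is None:
        groups = np.arange(len(x))
    train_idx, val_idx = subject_split(groups, cfg.split, cfg.seed)
    if len(val_idx) == 0:
        val_idx = train_idx

    opt = Adam(model.params(), lr=cfg.lr0, clip_norm=5.0)
    sched = PlateauScheduler(opt, cfg.plateau_patience, cfg.plateau_factor)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7247]))
    report = TrainingReport(metric_name="dice")
    best_val, stale = -np.inf, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses, dices = [], []
        for batch in _as_batches(order, cfg.batch_size):
            opt.zero_grad()
            p = model.forward(x[batch], train=True)
            loss, grad = _soft_dice_batch(p, y[batch])
            model.backward(grad)
            opt.step()
            losses.append(loss)
            dices.append(1.0 - loss)
        val_p = predict_proba(model, x[val_idx])
        val_loss, _ = _soft_dice_batch(val_p, y[val_idx])
        val_dice = float(np.mean([
            metrics.dice_coefficient(val_p[i, 0] > 0.5, y[val_idx][i, 0])
            for i in range(len(val_idx))]))
        val_acc = metrics.binary_accuracy(val_p.ravel(), y[val_idx].ravel())

        report.train_loss.append(float(np.mean(losses)))
        report.val_loss.append(val_loss)
        report.train_metric.append(float(np.mean(dices)))
        report.val_metric.append(val_dice)
        report.val_accuracy.append(val_acc)
        report.lr_trace.append(opt.lr)
        log.info("epoch %d: train loss %.4f, val dice %.4f, val acc %.4f, lr %g",
                 epoch + 1, report.train_loss[-1], val_dice, val_acc, opt.lr)

        sched.step(val_loss)
        if val_dice > best_val + 1e-5:
            best_val, stale = val_dice, 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                log.info("early stop at epoch %d (val dice plateau)", epoch + 1)
                break
    return report


def predict_proba(model: UNet, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Inference in batches; x is (N, 1, H, W) float in [0, 1]."""
    outs = [model.forward(x[i:i + batch_size], train=False)
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def segment(model: UNet, img: np.ndarray) -> np.ndarray:
    """Segment one preprocessed image into a binary {0,1} vein mask."""
    if img.shape != tuple(model.cfg.input_size):
        raise ValueError(f"expected {model.cfg.input_size} input, got {img.shape}")
    x = (img.astype(np.float32) / 255.0 if img.dtype == np.uint8
         else img.astype(np.float32))[None, None]
    p = model.forward(x, train=False)
    return (p[0, 0] > 0.5).astype(np.uint8)
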