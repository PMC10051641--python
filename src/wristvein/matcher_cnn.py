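"""Two-input CNN matcher: maps a pair of vein masks to a match probability.

Each input follows its own two-block convolutional pathway (conv 3x3 + ReLU,
2x2 max pool, 25% dropout; 1->32->64 filters, 18,816 trainable parameters
per pathway).  The pathway outputs are concatenated along channels and pass
through two more blocks (128->256->512), are flattened (8*8*512 = 32,768 at
the 128 x 128 working size), reduced by a 512-unit ReLU dense layer with
dropout and scored by a single sigmoid unit.  Total: 18,291,201 trainable
parameters.  The two pathways are identical in structure but do not share
weights, so the output is not guaranteed symmetric under input swap.

Training uses Adam with binary cross-entropy and per-epoch augmentation
resampling of both masks of every pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import metrics
from .nn import Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2D, ReLU, Sigmoid, Sequential
from .pairing import GENUINE, AugmentConfig, augment
from .training import TrainingReport

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CnnMatcherConfig:
    input_size: tuple = (128, 128)
    pathway_filters: tuple = (32, 64)
    merged_filters: tuple = (256, 512)
    dropout: float = 0.25
    dense_units: int = 512
    lr: float = 0.0003
    batch_size: int = 32
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % 16 or w % 16:
            raise ValueError("input size must be divisible by 16 (four 2x2 poolings)")


def _block(c_in, c_out, rng, drop_rng, rate, name):
    return Sequential(
        Conv2D(c_in, c_out, 3, rng=rng, name=name),
        ReLU(),
        MaxPool2D(),
        Dropout(rate, drop_rng),
    )


class CnnMatcher:
    def __init__(self, cfg: CnnMatcherConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC99]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0D]))
        f1, f2 = cfg.pathway_filters
        m1, m2 = cfg.merged_filters
        self.pathway_a = Sequential(
            _block(1, f1, rng, drop_rng, cfg.dropout, "pa.b1"),
            _block(f1, f2, rng, drop_rng, cfg.dropout, "pa.b2"),
        )
        self.pathway_b = Sequential(
            _block(1, f1, rng, drop_rng, cfg.dropout, "pb.b1"),
            _block(f1, f2, rng, drop_rng, cfg.dropout, "pb.b2"),
        )
        h, w = cfg.input_size
        flat = (h // 16) * (w // 16) * m2
        self.merged = Sequential(
            _block(2 * f2, m1, rng, drop_rng, cfg.dropout, "m.b1"),
            _block(m1, m2, rng, drop_rng, cfg.dropout, "m.b2"),
            Flatten(),
            Dense(flat, cfg.dense_units, rng=rng, name="fc1"),
            ReLU(),
            Dropout(cfg.dropout, drop_rng),
            Dense(cfg.dense_units, 1, rng=rng, name="fc2"),
            Sigmoid(),
        )
        self.flatten_length = flat
        log.info("CNN matcher built: %d trainable parameters (pathway %d, flatten %d)",
                 self.n_params(), self.pathway_params(), flat)

    def forward(self, xa, xb, train: bool = False):
        fa = self.pathway_a.forward(xa, train)
        fb = self.pathway_b.forward(xb, train)
        x = np.concatenate([fa, fb], axis=1)
        return self.merged.forward(x, train)

    def backward(self, grad):
        g = self.merged.backward(grad)
        c = g.shape[1] // 2
        self.pathway_a.backward(np.ascontiguousarray(g[:, :c]))
        self.pathway_b.backward(np.ascontiguousarray(g[:, c:]))

    def params(self):
        return self.pathway_a.params() + self.pathway_b.params() + self.merged.params()

    def bn_stats(self):
        return []

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def pathway_params(self) -> int:
        return sum(p.size for p in self.pathway_a.params())

    def config_dict(self) -> dict:
        d = asdict(self.cfg)
        d["model"] = "cnn_matcher"
        return d


def build_cnn_matcher(cfg: CnnMatcherConfig | None = None) -> CnnMatcher:
    return CnnMatcher(cfg or CnnMatcherConfig())


def parameter_audit(cfg: CnnMatcherConfig | None = None) -> list[dict]:
    """Closed-form parameter table, independent of the constructed graph.

    Convolutions count (k*k*C_in + 1) * C_out, dense layers (D_in + 1) * D_out;
    pooling and dropout carry no parameters.
    """
    cfg = cfg or CnnMatcherConfig()
    f1, f2 = cfg.pathway_filters
    m1, m2 = cfg.merged_filters
    h, w = cfg.input_size
    flat = (h // 16) * (w // 16) * m2
    rows = []

    def conv(name, c_in, c_out):
        rows.append({"layer": name, "kind": "conv3x3",
                     "params": (9 * c_in + 1) * c_out})

    for p in ("pathway_a", "pathway_b"):
        conv(f"{p}.conv1", 1, f1)
        conv(f"{p}.conv2", f1, f2)
    conv("merged.conv1", 2 * f2, m1)
    conv("merged.conv2", m1, m2)
    rows.append({"layer": "fc1", "kind": "dense", "params": (flat + 1) * cfg.dense_units})
    rows.append({"layer": "fc2", "kind": "dense", "params": (cfg.dense_units + 1) * 1})
    return rows


def _bce(p: np.ndarray, y: np.ndarray, eps: float = 1e-7):
    p = np.clip(p, eps, 1 - eps)
    loss = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
    grad = ((p - y) / (p * (1 - p))) / p.size
    return loss, grad.astype(np.float32)


def _pair_arrays(pairs, masks, size):
    """Resolve a pair manifest to float mask arrays at the working size."""
    from .preprocess import resize
    idx_a = pairs["index_a"].to_numpy()
    idx_b = pairs["index_b"].to_numpy()
    a = np.stack([resize(np.asarray(masks[i]), size, binary=True) for i in idx_a])
    b = np.stack([resize(np.asarray(masks[i]), size, binary=True) for i in idx_b])
    y = (pairs["label"] == GENUINE).to_numpy().astype(np.float32)
    return a.astype(np.float32), b.astype(np.float32), y


def train_cnn_matcher(model: CnnMatcher, train_pairs, val_pairs, masks,
                      cfg: CnnMatcherConfig | None = None,
                      aug: AugmentConfig | None = None,
                      epochs: int | None = None) -> TrainingReport:
    """Adam + binary cross-entropy on genuine/impostor mask pairs.

    ``masks`` is an indexable collection the manifests point into; both
    masks of each pair are augmented independently, re-drawn every epoch.
    """
    cfg = cfg or model.cfg
    if len(train_pairs) == 0:
        raise ValueError("empty pair set")
    epochs = epochs or cfg.epochs
    size = tuple(cfg.input_size)
    xa, xb, y = _pair_arrays(train_pairs, masks, size)
    va, vb, vy = _pair_arrays(val_pairs, masks, size) if len(val_pairs) else (None, None, None)

    opt = Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA06]))
    report = TrainingReport(metric_name="f1")
    for epoch in range(epochs):
        if aug is not None and (aug.per_epoch_resample or epoch == 0):
            ea = np.stack([augment(m, aug, rng) for m in xa])
            eb = np.stack([augment(m, aug, rng) for m in xb])
        else:
            ea, eb = xa, xb
        order = rng.permutation(len(y))
        losses, preds, labels = [], [], []
        for i in range(0, len(order), cfg.batch_size):
            batch = order[i:i + cfg.batch_size]
            opt.zero_grad()
            p = model.forward(ea[batch][:, None], eb[batch][:, None], train=True)
            loss, grad = _bce(p[:, 0], y[batch])
            model.backward(grad[:, None])
            opt.step()
            losses.append(loss)
            preds.extend(p[:, 0])
            labels.extend(y[batch])
        c = metrics.confusion_counts(np.array(preds) > 0.5, np.array(labels) > 0.5)
        report.train_loss.append(float(np.mean(losses)))
        report.train_metric.append(metrics.f1_score(c))
        if va is not None:
            vp = match_probability_batch(model, va, vb)
            vloss, _ = _bce(vp, vy)
            vc = metrics.confusion_counts(vp > 0.5, vy > 0.5)
            report.val_loss.append(vloss)
            report.val_metric.append(metrics.f1_score(vc))
            report.val_accuracy.append(metrics.binary_accuracy(vp, vy))
        else:
            report.val_loss.append(np.nan)
            report.val_metric.append(np.nan)
            report.val_accuracy.append(np.nan)
        report.lr_trace.append(opt.lr)
        log.info("cnn epoch %d: train loss %.4f, val acc %s", epoch + 1,
                 report.train_loss[-1], report.val_accuracy[-1])
    return report


def match_probability_batch(model: CnnMatcher, a: np.ndarray, b: np.ndarray,
                            batch_size: int = 16) -> np.ndarray:
    out = []
    for i in range(0, len(a), batch_size):
        p = model.forward(a[i:i + batch_size][:, None], b[i:i + batch_size][:, None],
                          train=False)
        out.append(p[:, 0])
    return np.concatenate(out)


def match_probability_cnn(model: CnnMatcher, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Probability in [0, 1] that the two masks come from the same wrist."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask dimensions differ")
    if mask_a.shape != tuple(model.cfg.input_size):
        raise ValueError(f"expected masks at {model.cfg.input_size}")
    p = model.forward(mask_a.astype(np.float32)[None, None],
                      mask_b.astype(np.float32)[None, None], train=False)
    return float(p[0, 0])
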