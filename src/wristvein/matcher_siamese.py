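"""Siamese verification network with contrastive loss.

One shared-weight embedding sub-network maps each binary vein mask to a
128-dimensional feature vector: an input batch-normalisation, three
convolutional blocks (3x3 conv with 64 filters -> batch norm -> ReLU -> 2x2
average pool -> dropout) and a fully connected block (flatten -> batch norm
-> dense 128 with ReLU).  A pair is compared by the Euclidean distance
between its two embeddings and trained with the contrastive loss

    L = mean((1 - Y) * d^2 + Y * max(M - d, 0)^2),

where Y = 0 marks a similar (genuine) pair and Y = 1 a dissimilar
(impostor) pair, and the margin M defaults to 1.  Verification accepts when
the distance falls at or below a threshold tau calibrated on validation
pairs; sigmoid(d) is also reported as a monotone match score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import metrics
from .nn import (Adam, AvgPool2D, BatchNorm1D, BatchNorm2D, Conv2D, Dense,
                 Dropout, Flatten, ReLU, Sequential)
from .pairing import GENUINE, AugmentConfig, augment
from .training import TrainingReport

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiameseConfig:
    input_size: tuple = (256, 256)
    conv_filters: int = 64
    n_blocks: int = 3
    embed_dim: int = 128
    dropout: float = 0.25
    margin: float = 1.0
    lr: float = 0.0003
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        h, w = self.input_size
        if h % (2 ** self.n_blocks) or w % (2 ** self.n_blocks):
            raise ValueError(f"input size must allow {self.n_blocks} 2x2 poolings")


@dataclass(frozen=True)
class MatchDecision:
    distance: float
    score: float        # sigmoid(distance), monotone increasing in distance
    threshold: float
    verdict: bool       # accept iff distance <= threshold

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


class SiameseEmbedding:
    """The shared sub-network; both branches are this single parameter store."""

    def __init__(self, cfg: SiameseConfig):
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51A]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5D0]))
        f = cfg.conv_filters
        h, w = cfg.input_size
        layers = [BatchNorm2D(1, name="bn0")]
        c_in = 1
        for i in range(cfg.n_blocks):
            layers += [
                Conv2D(c_in, f, 3, rng=rng, name=f"b{i}.conv"),
                BatchNorm2D(f, name=f"b{i}.bn"),
                ReLU(),
                AvgPool2D(),
                Dropout(cfg.dropout, drop_rng),
            ]
            c_in = f
        flat = (h // 2 ** cfg.n_blocks) * (w // 2 ** cfg.n_blocks) * f
        layers += [
            Flatten(),
            BatchNorm1D(flat, name="bn_flat"),
            Dense(flat, cfg.embed_dim, rng=rng, name="fc"),
            ReLU(),
        ]
        self.net = Sequential(*layers)
        log.info("Siamese sub-network built: %d trainable parameters "
                 "(embedding dim %d)", self.n_params(), cfg.embed_dim)

    def forward(self, x, train: bool = False):
        return self.net.forward(x, train)

    def backward(self, grad):
        return self.net.backward(grad)

    def params(self):
        return self.net.params()

    def bn_stats(self):
        out = []
        for layer in self.net.layers:
            if isinstance(layer, (BatchNorm1D, BatchNorm2D)):
                out.append((layer.running_mean, layer.running_var))
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def config_dict(self) -> dict:
        d = asdict(self.cfg)
        d["model"] = "siamese"
        return d


def build_subnetwork(cfg: SiameseConfig | None = None) -> SiameseEmbedding:
    return SiameseEmbedding(cfg or SiameseConfig())


def embed_batch(model: SiameseEmbedding, masks: np.ndarray,
                batch_size: int = 32) -> np.ndarray:
    """(N, H, W) binary masks -> (N, 128) embeddings, inference mode."""
    x = masks.astype(np.float32)
    out = [model.forward(x[i:i + batch_size][:, None], train=False)
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def embed_pair(model: SiameseEmbedding, mask_a: np.ndarray, mask_b: np.ndarray):
    """Both embeddings from the single shared model; order-equivariant."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask dimensions differ")
    e = embed_batch(model, np.stack([mask_a, mask_b]))
    return e[0], e[1]


def euclidean_distance(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(ea, dtype=np.float64)
                          - np.asarray(eb, dtype=np.float64), axis=-1)


def contrastive_loss(d, y, margin: float = 1.0) -> float:
    """mean((1-y) d^2 + y max(M - d, 0)^2); y=0 similar, y=1 dissimilar."""
    d = np.asarray(d, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    hinge = np.maximum(margin - d, 0.0)
    return float(np.mean((1.0 - y) * d ** 2 + y * hinge ** 2))


def decide(d: float, tau: float) -> MatchDecision:
    """Accept iff d <= tau (boundary inclusive); sigmoid(d) logged as score."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if tau <= 0:
        raise ValueError("threshold must be > 0")
    score = float(1.0 / (1.0 + np.exp(-d)))
    return MatchDecision(distance=float(d), score=score, threshold=float(tau),
                         verdict=bool(d <= tau))


def _pair_arrays(pairs, masks, size):
    from .preprocess import resize
    a = np.stack([resize(np.asarray(masks[i]), size, binary=True)
                  for i in pairs["index_a"].to_numpy()])
    b = np.stack([resize(np.asarray(masks[i]), size, binary=True)
                  for i in pairs["index_b"].to_numpy()])
    # loss convention: y = 0 for genuine/similar, 1 for impostor/dissimilar
    y = (pairs["label"] != GENUINE).to_numpy().astype(np.float64)
    return a.astype(np.float32), b.astype(np.float32), y


def pair_distances(model: SiameseEmbedding, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return euclidean_distance(embed_batch(model, a), embed_batch(model, b))


def evaluate_pairs(model: SiameseEmbedding, a, b, y_dissimilar):
    """Distances + threshold calibrated to maximise F1 on these pairs.

    Returns (distances, tau, f1, accuracy).  Genuine is the positive class.
    """
    d = pair_distances(model, a, b)
    genuine = 1.0 - np.asarray(y_dissimilar)
    tau, f1 = metrics.calibrate_threshold(d, genuine)
    acc = metrics.binary_accuracy(d <= tau, genuine > 0.5)
    return d, tau, f1, acc


def train_siamese(model: SiameseEmbedding, train_pairs, val_pairs, masks,
                  cfg: SiameseConfig | None = None,
                  aug: AugmentConfig | None = None,
                  epochs: int | None = None) -> TrainingReport:
    """Minimise the contrastive loss with Adam; per-epoch augmentation.

    Per epoch the report carries train/val contrastive loss and, on the
    validation pairs, F1 and accuracy at a validation-calibrated threshold.
    """
    cfg = cfg or model.cfg
    if len(train_pairs) == 0:
        raise ValueError("empty pair set")
    epochs = epochs or cfg.epochs
    size = tuple(cfg.input_size)
    xa, xb, y = _pair_arrays(train_pairs, masks, size)
    has_val = len(val_pairs) > 0
    if has_val:
        va, vb, vy = _pair_arrays(val_pairs, masks, size)

    opt = Adam(model.params(), lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E4]))
    report = TrainingReport(metric_name="f1")
    m = cfg.margin
    for epoch in range(epochs):
        if aug is not None and (aug.per_epoch_resample or epoch == 0):
            ea = np.stack([augment(mk, aug, rng) for mk in xa])
            eb = np.stack([augment(mk, aug, rng) for mk in xb])
        else:
            ea, eb = xa, xb
        order = rng.permutation(len(y))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch = order[i:i + cfg.batch_size]
            nb = len(batch)
            opt.zero_grad()
            # run both sides through the shared network as one batch
            x = np.concatenate([ea[batch], eb[batch]])[:, None]
            emb = model.forward(x, train=True)
            e1, e2 = emb[:nb], emb[nb:]
            diff = e1 - e2
            d = np.sqrt((diff ** 2).sum(axis=1) + 1e-12)
            yb = y[batch]
            hinge = np.maximum(m - d, 0.0)
            loss = float(np.mean((1 - yb) * d ** 2 + yb * hinge ** 2))
            # dL/dd = (2 (1-y) d - 2 y max(M-d,0)) / nb ; dd/de1 = diff / d
            dld = (2 * (1 - yb) * d - 2 * yb * hinge) / nb
            ge1 = (dld / d)[:, None] * diff
            model.backward(np.concatenate([ge1, -ge1]).astype(np.float32))
            opt.step()
            losses.append(loss)
        report.train_loss.append(float(np.mean(losses)))
        report.train_metric.append(np.nan)
        if has_val:
            d_val, tau, f1, acc = evaluate_pairs(model, va, vb, vy)
            report.val_loss.append(contrastive_loss(d_val, vy, m))
            report.val_metric.append(f1)
            report.val_accuracy.append(acc)
            report.val_genuine_distance.append(float(d_val[vy == 0].mean()))
            report.val_impostor_distance.append(float(d_val[vy == 1].mean()))
        else:
            report.val_loss.append(np.nan)
            report.val_metric.append(np.nan)
            report.val_accuracy.append(np.nan)
            report.val_genuine_distance.append(np.nan)
            report.val_impostor_distance.append(np.nan)
        report.lr_trace.append(opt.lr)
        log.info("siamese epoch %d: train loss %.4f, val f1 %s", epoch + 1,
                 report.train_loss[-1], report.val_metric[-1])
    return report
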