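"""Shared training utilities: per-epoch reports, plateau LR schedule, checkpoints."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class TrainingReport:
    """Per-epoch training history; one list entry per completed epoch."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    train_metric: list = field(default_factory=list)
    val_metric: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)
    # matcher trainings also trace the genuine/impostor mean val distances
    val_genuine_distance: list = field(default_factory=list)
    val_impostor_distance: list = field(default_factory=list)
    metric_name: str = ""

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, self.epochs_run + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            f"train_{self.metric_name}": self.train_metric,
            f"val_{self.metric_name}": self.val_metric,
            "val_accuracy": self.val_accuracy,
            "lr": self.lr_trace,
        })


class PlateauScheduler:
    """Multiply the LR by ``factor`` when the monitored loss has not improved
    for ``patience`` epochs."""

    def __init__(self, optimizer, patience: int = 10, factor: float = 0.1,
                 min_delta: float = 1e-5):
        self.opt = optimizer
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def step(self, value: float) -> None:
        if value < self.best - self.min_delta:
            self.best = value
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.opt.lr *= self.factor
                self.stale = 0


def save_model(model, path) -> None:
    """Persist parameters + batchnorm running statistics + config sidecar."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"p{i}"] = p.value
    for i, (mean, var) in enumerate(model.bn_stats()):
        arrays[f"bn{i}_mean"] = mean
        arrays[f"bn{i}_var"] = var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = path.with_suffix(".json")
    cfg = model.config_dict()
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_weights(model, path) -> None:
    """Load arrays saved by :func:`save_model` into an existing model."""
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i}"]
    for i, (mean, var) in enumerate(model.bn_stats()):
        mean[...] = data[f"bn{i}_mean"]
        var[...] = data[f"bn{i}_var"]
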