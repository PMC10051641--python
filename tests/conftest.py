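"""Shared fixtures.

The recovery fixtures train the real networks on a synthetic dataset at a
reduced working resolution (64 x 64, 32 subjects = 64 wrists) so the whole
suite stays within a desktop-CPU budget; they are session-scoped because
several modules probe the same trained models.
"""

from __future__ import annotations

import numpy as np
import pytest

from wristvein.matcher_cnn import CnnMatcher, CnnMatcherConfig, train_cnn_matcher
from wristvein.matcher_siamese import (SiameseConfig, SiameseEmbedding,
                                       contrastive_loss, evaluate_pairs,
                                       train_siamese)
from wristvein.matcher_siamese import _pair_arrays as siamese_pair_arrays
from wristvein.pairing import AugmentConfig, build_pairs
from wristvein.preprocess import PreprocessConfig, preprocess_pipeline, resize
from wristvein.synthetic import generate_dataset
from wristvein.unet import UNet, UNetConfig, predict_proba, subject_split, train_unet
from wristvein import metrics

FRAME = (128, 128)          # rendering frame of the synthetic captures
WORK = (64, 64)             # working resolution for the recovery trainings
DATA_SEED = 21
N_SUBJECTS = 32             # 64 wrists, 128 images


@pytest.fixture(scope="session")
def dataset():
    """32 subjects x 2 wrists x 2 sessions of synthetic captures."""
    return generate_dataset(N_SUBJECTS, 2, seed=DATA_SEED, frame=FRAME)


@pytest.fixture(scope="session")
def prepped(dataset):
    """CLAHE-preprocessed images and ground-truth masks at the working size."""
    reg, imgs, masks = dataset
    pc = PreprocessConfig(target_size=WORK)
    x = np.stack([preprocess_pipeline(im, pc) for im in imgs])
    y = np.stack([resize(m, WORK, binary=True) for m in masks])
    return reg, x, y


@pytest.fixture(scope="session")
def pairs(dataset):
    reg, _imgs, _masks = dataset
    return build_pairs(reg, 0.8, seed=DATA_SEED)


def _val_dice(model, x, y, val_idx):
    xv = (x.astype(np.float32) / 255.0)[val_idx][:, None]
    p = predict_proba(model, xv)
    return float(np.mean([metrics.dice_coefficient(p[i, 0] > 0.5, y[val_idx][i])
                          for i in range(len(val_idx))]))


@pytest.fixture(scope="session")
def unet_recovery(prepped):
    """U-Net trained 12 epochs on the synthetic set, plus its untrained twin's
    validation Dice as the baseline."""
    reg, x, y = prepped
    cfg = UNetConfig(input_size=WORK, epochs=12, seed=3)
    groups = reg["subject_id"].to_numpy()
    _tr, val_idx = subject_split(groups, cfg.split, cfg.seed)
    untrained = UNet(cfg)
    untrained_dice = _val_dice(untrained, x, y, val_idx)
    model = UNet(cfg)
    report = train_unet(model, x, y, cfg, groups=groups)
    return {"model": model, "report": report, "cfg": cfg,
            "untrained_dice": untrained_dice, "val_idx": val_idx,
            "x": x, "y": y}


def _augmented_protocol_f1(model, va, vb, vy, aug, seeds=(99, 100, 101)):
    """Mean calibrated-threshold F1 over several augmentation draws of the
    validation pairs (augmentations are applied before testing as well)."""
    from wristvein.pairing import augment
    scores = []
    for s in seeds:
        rng = np.random.default_rng(s)
        aa = np.stack([augment(m, aug, rng) for m in va])
        ab = np.stack([augment(m, aug, rng) for m in vb])
        _d, _tau, f1, _acc = evaluate_pairs(model, aa, ab, vy)
        scores.append(f1)
    return float(np.mean(scores))


@pytest.fixture(scope="session")
def siamese_recovery(dataset, pairs):
    _reg, _imgs, masks = dataset
    train_p, test_p = pairs
    cfg = SiameseConfig(input_size=WORK, seed=7)
    aug = AugmentConfig(zoom_range=(0.9, 1.1))
    va, vb, vy = siamese_pair_arrays(test_p, masks, WORK)
    model = SiameseEmbedding(cfg)
    d0, _tau0, f1_0, _acc0 = evaluate_pairs(model, va, vb, vy)
    untrained_aug_f1 = _augmented_protocol_f1(model, va, vb, vy, aug)
    untrained_loss = contrastive_loss(d0, vy, cfg.margin)
    report = train_siamese(model, train_p, test_p, masks, cfg, aug, epochs=12)
    d, tau, f1, acc = evaluate_pairs(model, va, vb, vy)
    trained_aug_f1 = _augmented_protocol_f1(model, va, vb, vy, aug)
    return {"model": model, "report": report, "cfg": cfg,
            "untrained": {"distances": d0, "f1": f1_0, "loss": untrained_loss,
                          "aug_f1": untrained_aug_f1},
            "trained": {"distances": d, "tau": tau, "f1": f1, "acc": acc,
                        "loss": contrastive_loss(d, vy, cfg.margin),
                        "aug_f1": trained_aug_f1},
            "val_labels_dissimilar": vy, "val_masks": (va, vb)}


@pytest.fixture(scope="session")
def cnn_recovery(dataset, pairs):
    _reg, _imgs, masks = dataset
    train_p, test_p = pairs
    cfg = CnnMatcherConfig(input_size=WORK, seed=7)
    aug = AugmentConfig(zoom_range=(0.9, 1.1))
    model = CnnMatcher(cfg)
    report = train_cnn_matcher(model, train_p, test_p, masks, cfg, aug, epochs=10)
    return {"model": model, "report": report, "cfg": cfg, "test_pairs": test_p,
            "masks": masks}
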