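"""Genuine/impostor pair construction and training-time mask augmentation.

Each wrist (a subject side) contributes exactly two pairs: its session-1
image paired with its own session-2 image (genuine) and with a random
non-matching session-2 image from the same split (impostor).  The split is
made at wrist level before pairing, so no identity leaks across splits, and
genuine:impostor stays 1:1.

Augmentation composes a random rotation, zoom and translation into one
affine transform, resampled anew every epoch; nearest-neighbour resampling
keeps masks binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import apply_affine

log = logging.getLogger(__name__)

GENUINE, IMPOSTOR = "genuine", "impostor"


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation envelope: rotation +-15 deg, zoom scale in
    ``zoom_range``, translation +-10% both axes, resampled per epoch.

    The default zoom range [0.40, 0.60] follows the stated protocol
    literally (patterns rendered at roughly half scale); [0.9, 1.1] is the
    recommended override for scale-preserving jitter.
    """

    rotation_deg: float = 15.0
    zoom_range: tuple = (0.40, 0.60)
    translate_frac: float = 0.10
    per_epoch_resample: bool = True

    def __post_init__(self):
        if self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("zoom_range must be (lo, hi)")
        if self.zoom_range[1] < 0.8 or self.zoom_range[0] > 1.2:
            log.info("zoom_range %s rescales patterns far from unit scale "
                     "(literal protocol); consider (0.9, 1.1)", self.zoom_range)


def build_pairs(registry: pd.DataFrame, split_frac: float = 0.8,
                seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (train_pairs, test_pairs) manifests from a session registry.

    ``registry`` needs columns subject_id, wrist, session (sessions 1 and 2
    are used).  Each returned row has index_a/index_b (row positions in the
    registry), the identity of both sides and a genuine/impostor label.
    """
    reg = registry.reset_index(drop=True)
    wrist_ids = reg[["subject_id", "wrist"]].drop_duplicates()
    wrists = [tuple(r) for r in wrist_ids.itertuples(index=False)]
    if len(wrists) < 2:
        raise ValueError("impostor pairing needs at least 2 wrists")
    sessions = reg.groupby(["subject_id", "wrist"])["session"].nunique()
    if (sessions < 2).any():
        raise ValueError("every wrist needs at least 2 sessions")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A125]))
    perm = rng.permutation(len(wrists))
    n_train = int(round(split_frac * len(wrists)))
    train_w = [wrists[i] for i in perm[:n_train]]
    test_w = [wrists[i] for i in perm[n_train:]]
    if split_frac < 1.0 and len(test_w) < 2 and len(train_w) > 2:
        # keep the test side pairable
        test_w.append(train_w.pop())

    lookup = {}
    for idx, row in reg.iterrows():
        lookup[(row.subject_id, row.wrist, row.session)] = idx

    def pairs_for(split_wrists):
        rows = []
        for sid, wrist in split_wrists:
            a = lookup[(sid, wrist, 1)]
            b = lookup[(sid, wrist, 2)]
            rows.append({"index_a": a, "index_b": b,
                         "subject_a": sid, "wrist_a": wrist,
                         "subject_b": sid, "wrist_b": wrist,
                         "label": GENUINE})
            others = [w for w in split_wrists if w != (sid, wrist)]
            osid, owrist = others[rng.integers(len(others))]
            rows.append({"index_a": a, "index_b": lookup[(osid, owrist, 2)],
                         "subject_a": sid, "wrist_a": wrist,
                         "subject_b": osid, "wrist_b": owrist,
                         "label": IMPOSTOR})
        return pd.DataFrame(rows)

    train_pairs = pairs_for(train_w)
    test_pairs = pairs_for(test_w) if test_w else pd.DataFrame(
        columns=["index_a", "index_b", "subject_a", "wrist_a",
                 "subject_b", "wrist_b", "label"])
    return train_pairs, test_pairs


def augment(mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """One random affine draw applied to a binary mask (stays binary,
    out-of-frame filled with 0)."""
    rot = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    scale = rng.uniform(*cfg.zoom_range)
    tr = rng.uniform(-cfg.translate_frac, cfg.translate_frac)
    tc = rng.uniform(-cfg.translate_frac, cfg.translate_frac)
    if rot == 0.0 and scale == 1.0 and tr == 0.0 and tc == 0.0:
        return mask.copy()
    out = apply_affine(mask, rot, (tr, tc), scale, binary=True, cval=0.0)
    return out.astype(mask.dtype)


def pair_manifest_to_csv(pairs: pd.DataFrame, registry: pd.DataFrame, path,
                         split: str) -> pd.DataFrame:
    """Write a pair manifest as CSV with resolved mask paths."""
    out = pairs.copy()
    out["path_a"] = registry["mask_path"].to_numpy()[out["index_a"].to_numpy()]
    out["path_b"] = registry["mask_path"].to_numpy()[out["index_b"].to_numpy()]
    out["split"] = split
    out[["path_a", "path_b", "label", "split"]].to_csv(path, index=False)
    return out
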