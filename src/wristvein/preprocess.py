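"""Preprocessing: grayscale conversion, resize to working resolution, CLAHE.

Raw NIR wrist captures are low-contrast: vein ridges sit only a few grey
levels below the skin background.  The pipeline resizes every image to the
segmentation working resolution (256 x 256 by default; aspect is not
preserved since inputs are already region-of-interest crops) and then applies
contrast-limited adaptive histogram equalisation, which equalises per tile
while clipping each tile histogram and redistributing the clipped mass so
flat skin regions are not over-amplified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform


@dataclass(frozen=True)
class PreprocessConfig:
    """CLAHE with an 8 x 8 tile grid and clip threshold 6 (on 256 histogram
    bins; the threshold is divided by ``nbins`` to obtain the normalised
    clip limit convention)."""

    target_size: tuple = (256, 256)
    clahe_tile: tuple = (8, 8)
    clahe_clip: float = 6.0
    nbins: int = 256

    def __post_init__(self):
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if min(self.target_size) < 16:
            raise ValueError("target_size must be at least 16 x 16")


def as_gray_u8(img: np.ndarray) -> np.ndarray:
    """Coerce an image to single-channel uint8; 16-bit inputs are rescaled."""
    img = np.asarray(img)
    if img.ndim == 3:
        if img.shape[2] not in (1, 3, 4):
            raise ValueError(f"cannot interpret image of shape {img.shape} as grayscale")
        if img.shape[2] == 1:
            img = img[:, :, 0]
        else:
            img = img[:, :, :3].mean(axis=2)
    elif img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if img.dtype == np.uint16:
        img = img.astype(np.float64) / 257.0
    return np.clip(np.round(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)


def resize(img: np.ndarray, target: tuple, *, binary: bool = False) -> np.ndarray:
    """Resize to ``target`` (H, W).  Bilinear for intensity images,
    nearest-neighbour for binary masks so binarity is preserved."""
    if min(target) < 16:
        raise ValueError("target size must be at least 16 x 16")
    if tuple(img.shape[:2]) == tuple(target):
        return img.copy()
    order = 0 if binary else 1
    out = transform.resize(img.astype(float), target, order=order,
                           preserve_range=True, anti_aliasing=not binary)
    if binary:
        return (out > 0.5).astype(img.dtype)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def clahe(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on an 8-bit image."""
    cfg = cfg or PreprocessConfig()
    if img.ndim != 2:
        raise ValueError("CLAHE expects a single-channel image")
    img = np.ascontiguousarray(img, dtype=np.uint8)
    if img.min() == img.max():
        return img.copy()  # no contrast to amplify
    h, w = img.shape
    ty, tx = cfg.clahe_tile
    kernel = (max(1, h // ty), max(1, w // tx))
    clip = min(1.0, cfg.clahe_clip / cfg.nbins)
    out = exposure.equalize_adapthist(img, kernel_size=kernel,
                                      clip_limit=clip, nbins=cfg.nbins)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def preprocess_pipeline(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Resize then CLAHE, in that order; deterministic."""
    cfg = cfg or PreprocessConfig()
    return clahe(resize(as_gray_u8(img), cfg.target_size), cfg)
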