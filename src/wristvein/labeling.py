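"""Classical vein-mask generation (pseudo ground truth for the segmenter).

Chain: non-local-means denoising -> grayscale morphological opening ->
global histogram equalisation -> binarisation (Otsu, veins = darker class)
-> iterated erosion/dilation until a fixed point.  The output masks are
approximate but good enough to supervise the U-Net, which then produces
cleaner masks than this chain itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import exposure, filters, morphology, restoration

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelingConfig:
    nlm_strength: float = 8.0        # NLM filter strength h, grey levels
    opening_radius: int = 1          # structuring element: disk(1) ~ 3x3 ellipse
    morph_max_iter: int = 50
    binarize_threshold: str = "quantile"   # "quantile" or "otsu"
    binarize_quantile: float = 0.12  # fraction of darkest pixels taken as vein
    dark_veins: bool = True          # mask marks the dark class (NIR convention)

    def __post_init__(self):
        if self.nlm_strength <= 0 or self.opening_radius < 1 or self.morph_max_iter < 1:
            raise ValueError("LabelingConfig values must be positive")


def denoise(img: np.ndarray, cfg: LabelingConfig | None = None) -> np.ndarray:
    """Non-local-means denoising; reduces noise variance on flat regions."""
    cfg = cfg or LabelingConfig()
    img = np.ascontiguousarray(img, dtype=np.uint8)
    out = restoration.denoise_nl_means(
        img.astype(np.float64) / 255.0,
        h=cfg.nlm_strength / 255.0,
        sigma=cfg.nlm_strength / 255.0,
        patch_size=5, patch_distance=6, fast_mode=True,
    )
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def open_morph(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological opening (erosion then dilation) with a disk element."""
    footprint = morphology.disk(radius)
    if footprint.shape[0] > min(img.shape) or footprint.shape[1] > min(img.shape):
        raise ValueError("structuring element larger than image")
    return morphology.opening(img, footprint)


def equalize(img: np.ndarray) -> np.ndarray:
    """Global (non-adaptive) histogram equalisation to [0, 255]."""
    img = np.ascontiguousarray(img, dtype=np.uint8)
    if img.min() == img.max():
        return img.copy()
    out = exposure.equalize_hist(img, nbins=256)
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def _binarize(img: np.ndarray, cfg: LabelingConfig) -> np.ndarray:
    # A global histogram equalisation flattens the intensity histogram, so a
    # between-class-variance criterion (Otsu) degenerates towards a 50% cut.
    # The default therefore takes the darkest fixed quantile, a vessel-density
    # prior; Otsu remains available for non-equalised inputs.
    if cfg.binarize_threshold == "otsu":
        t = filters.threshold_otsu(img)
        return img < t if cfg.dark_veins else img > t
    q = cfg.binarize_quantile if cfg.dark_veins else 1.0 - cfg.binarize_quantile
    t = np.quantile(img, q)
    return img <= t if cfg.dark_veins else img >= t


def iterative_refine(img: np.ndarray, cfg: LabelingConfig | None = None) -> np.ndarray:
    """Binarise then alternate erosion/dilation until no pixel changes.

    Each round is one morphological opening; opening is idempotent, so the
    loop converges quickly, but a hard iteration cap guarantees termination
    (a warning is logged if it is hit).
    """
    cfg = cfg or LabelingConfig()
    if set(np.unique(img)) <= {0, 1}:
        mask = img.astype(bool)
    else:
        mask = _binarize(img, cfg)
    footprint = morphology.disk(cfg.opening_radius)
    for _ in range(cfg.morph_max_iter):
        new = morphology.dilation(morphology.erosion(mask, footprint), footprint)
        if np.array_equal(new, mask):
            mask = new
            break
        mask = new
    else:
        log.warning("iterative_refine did not converge within %d iterations", cfg.morph_max_iter)
    return mask.astype(np.uint8)


def generate_mask(img: np.ndarray, cfg: LabelingConfig | None = None) -> np.ndarray:
    """Full chain: denoise -> open -> equalise -> iterative refinement.

    Returns a binary {0,1} mask of the same dimensions as the input.
    """
    cfg = cfg or LabelingConfig()
    x = denoise(img, cfg)
    x = open_morph(x, cfg.opening_radius)
    x = equalize(x)
    return iterative_refine(x, cfg)
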