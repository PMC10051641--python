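"""Synthetic wrist-vein dataset generator.

Emulates the structure of a two-session wrist-vein capture campaign
(N subjects x 2 wrists x S sessions, one image per session): dark tree-like
vein ridges on a brighter, low-contrast skin background with a smooth
illumination gradient, sensor noise, optical blur and a small session-to-
session pose jitter.  Ground-truth vessel masks are rendered alongside every
image, which makes the segmentation and matching stages trainable and
testable without any external data.

Vein trees are grown by a biased random branching walk; each (subject, wrist)
owns an independent tree derived hierarchically from one root seed, so adding
subjects never perturbs existing ones and the same spec always regenerates
the same anatomy.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology, transform

WRISTS = ("left", "right")


@dataclass(frozen=True)
class SubjectSpec:
    """Identity of one wrist's vascular pattern."""

    subject_id: str
    wrist: str
    seed: int
    n_sessions: int = 2

    def __post_init__(self):
        if self.wrist not in WRISTS:
            raise ValueError(f"wrist must be one of {WRISTS}, got {self.wrist!r}")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass
class VeinTree:
    """Connected acyclic vascular tree in pixel (row, col) coordinates."""

    nodes: np.ndarray            # (n, 2) float, row/col
    edges: list                  # (parent_idx, child_idx) pairs
    radii: np.ndarray            # per-edge vessel half-width, px
    frame: tuple                 # (H, W) the tree was grown in

    def total_length(self) -> float:
        p = self.nodes[[e[0] for e in self.edges]]
        c = self.nodes[[e[1] for e in self.edges]]
        return float(np.linalg.norm(p - c, axis=1).sum())

    def n_branch_points(self) -> int:
        counts = np.bincount([e[0] for e in self.edges], minlength=len(self.nodes))
        return int((counts >= 2).sum())


@dataclass(frozen=True)
class SceneParams:
    """Rendering parameters for one synthetic capture.

    Intensities are on the 8-bit scale.  Veins are darker than skin (NIR
    absorption by haemoglobin); ``vein_contrast`` is the intensity drop at
    the vessel centreline and is deliberately small relative to the
    background so that raw images are low-contrast and CLAHE has work to do.
    ``session_jitter`` is (max rotation deg, max translation fraction,
    (scale lo, scale hi)) — within the augmentation envelope matchers train
    under, so they can compensate.
    """

    background_level: float = 170.0
    gradient_amp: float = 20.0
    vein_contrast: float = 40.0
    noise_sigma: float = 6.0
    blur_sigma: float = 1.0
    session_jitter: tuple = (10.0, 0.05, (0.95, 1.05))

    def __post_init__(self):
        if self.vein_contrast < 0:
            raise ValueError("vein_contrast must be >= 0")


def _stable_hash(*parts) -> list[int]:
    """Deterministic, platform-independent entropy words from mixed values."""
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode("utf8")))
        else:
            out.append(int(p) & 0xFFFFFFFF)
    return out


def _rng_for(*parts) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(_stable_hash(*parts)))


def make_registry(n_subjects: int, n_sessions: int, seed: int) -> pd.DataFrame:
    """Expand (n_subjects x 2 wrists x n_sessions) into per-image records.

    Mirrors the bookkeeping of a two-session capture campaign: 160 subjects
    with two wrists imaged in two sessions give 640 records.
    """
    if n_subjects < 1 or n_sessions < 1:
        raise ValueError("n_subjects and n_sessions must be >= 1")
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:04d}"
        for wrist in WRISTS:
            for session in range(1, n_sessions + 1):
                rows.append({
                    "subject_id": sid,
                    "wrist": wrist,
                    "session": session,
                    "seed": seed,
                    "image_path": "",
                    "mask_path": "",
                })
    return pd.DataFrame(rows)


def grow_vein_tree(spec: SubjectSpec, frame: tuple = (256, 256)) -> VeinTree:
    """Grow a subject-unique vascular tree by a biased random branching walk.

    A trunk enters from a border region and wanders across the frame; at 2-4
    branching generations it splits into two children with ~+-30 deg angle
    jitter.  Vessel half-widths start at 2-3 px and taper towards the leaves.
    """
    h, w = frame
    if h < 64 or w < 64:
        raise ValueError("frame must be at least 64 x 64")
    rng = _rng_for(spec.seed, spec.subject_id, spec.wrist, "tree")

    nodes: list = []
    edges: list = []
    radii: list = []

    def walk(start, angle, length, radius, generation, max_gen):
        """Random walk one branch; returns index of its last node."""
        step = 7.0
        n_steps = max(3, int(length / step))
        idx = len(nodes)
        nodes.append(np.asarray(start, dtype=float))
        pos = np.asarray(start, dtype=float)
        for s in range(n_steps):
            angle += rng.uniform(-0.18, 0.18)
            nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
            # steer back inside instead of leaving the frame
            if not (4 <= nxt[0] < h - 4 and 4 <= nxt[1] < w - 4):
                centre = np.array([h / 2, w / 2])
                angle = np.arctan2(*(centre - pos)) + rng.uniform(-0.3, 0.3)
                nxt = pos + step * np.array([np.sin(angle), np.cos(angle)])
                nxt[0] = np.clip(nxt[0], 4, h - 5)
                nxt[1] = np.clip(nxt[1], 4, w - 5)
            nodes.append(nxt)
            edges.append((idx + s, idx + s + 1))
            taper = 1.0 - 0.15 * (s + 1) / n_steps
            radii.append(max(1.0, radius * taper))
            pos = nxt
        end_idx = idx + n_steps
        if generation < max_gen:
            spread = rng.uniform(0.35, 0.65)  # ~+-30 deg with jitter
            for sign in (-1.0, 1.0):
                child_angle = angle + sign * spread + rng.uniform(-0.15, 0.15)
                child_len = length * rng.uniform(0.55, 0.75)
                child_r = max(1.0, radius * 0.78)
                cidx = walk(nodes[end_idx], child_angle, child_len, child_r,
                            generation + 1, max_gen)
                edges.append((end_idx, cidx))
                radii.append(max(1.0, radius * 0.78))
        return idx

    max_gen = int(rng.integers(2, 5))
    side = rng.integers(0, 4)
    margin = 8.0
    if side == 0:
        start = (margin, rng.uniform(0.2, 0.8) * w)
        angle0 = 0.0 + rng.uniform(-0.4, 0.4)          # heading down
    elif side == 1:
        start = (h - margin, rng.uniform(0.2, 0.8) * w)
        angle0 = np.pi + rng.uniform(-0.4, 0.4)        # heading up
    elif side == 2:
        start = (rng.uniform(0.2, 0.8) * h, margin)
        angle0 = np.pi / 2 + rng.uniform(-0.4, 0.4)    # heading right
    else:
        start = (rng.uniform(0.2, 0.8) * h, w - margin)
        angle0 = -np.pi / 2 + rng.uniform(-0.4, 0.4)   # heading left
    root_radius = rng.uniform(2.2, 3.0)
    walk(start, angle0, 0.55 * max(h, w), root_radius, 0, max_gen)

    tree = VeinTree(np.array(nodes), edges, np.array(radii), (h, w))
    assert tree.total_length() >= 0.5 * max(h, w)
    return tree


def rasterize_tree(tree: VeinTree) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a tree to (vessel mask, centreline mask), both uint8 {0,1}."""
    h, w = tree.frame
    centre = np.zeros((h, w), dtype=bool)
    # group centreline pixels by quantised radius, then dilate per group
    by_radius: dict = {}
    for (pi, ci), r in zip(tree.edges, tree.radii):
        p, c = tree.nodes[pi], tree.nodes[ci]
        n = max(2, int(np.ceil(np.linalg.norm(c - p) / 0.5)))
        ts = np.linspace(0.0, 1.0, n)
        pts = p[None, :] * (1 - ts[:, None]) + c[None, :] * ts[:, None]
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        key = int(round(r * 2))  # 0.5 px radius bins
        grp = by_radius.setdefault(key, np.zeros((h, w), dtype=bool))
        grp[rr, cc] = True
        centre[rr, cc] = True
    mask = np.zeros((h, w), dtype=bool)
    for key, grp in by_radius.items():
        r = key / 2.0
        mask |= morphology.dilation(grp, morphology.disk(max(1, int(round(r)))))
    return mask.astype(np.uint8), centre.astype(np.uint8)


def session_jitter_params(params: SceneParams, session_seed: int):
    """The affine pose perturbation a given session seed will apply.

    Exposed so that callers (and tests) can invert the known jitter.
    Returns (rotation_deg, (translate_r, translate_c), scale).
    """
    rng = _rng_for(session_seed, "jitter")
    rot_max, trans_max, (s_lo, s_hi) = params.session_jitter
    rot = rng.uniform(-rot_max, rot_max)
    tr = rng.uniform(-trans_max, trans_max)
    tc = rng.uniform(-trans_max, trans_max)
    scale = rng.uniform(s_lo, s_hi)
    return rot, (tr, tc), scale


def _centered_affine(shape, rot_deg, translate_frac, scale) -> transform.AffineTransform:
    h, w = shape
    tr, tc = translate_frac
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # pixel-centre, (x, y)
    shift = transform.AffineTransform(translation=-centre)
    core = transform.AffineTransform(rotation=np.deg2rad(rot_deg), scale=scale)
    unshift = transform.AffineTransform(translation=centre + np.array([tc * w, tr * h]))
    return shift + core + unshift


def apply_affine(img: np.ndarray, rot_deg: float, translate_frac, scale: float,
                 *, binary: bool = False, cval: float = 0.0,
                 inverse: bool = False) -> np.ndarray:
    """Apply a centred rotation/scale/translation; nearest-neighbour for masks.

    With ``inverse=True`` the exact inverse warp is applied, which lets a
    caller undo a known session jitter (registration by ground truth).
    """
    tf = _centered_affine(img.shape, rot_deg, translate_frac, scale)
    order = 0 if binary else 1
    mode = "constant" if binary else "edge"
    inv_map = tf if inverse else tf.inverse
    out = transform.warp(img.astype(float), inv_map, order=order,
                         mode=mode, cval=cval, preserve_range=True)
    return out


def render_session(tree: VeinTree, params: SceneParams, session_seed: int):
    """Render one capture of a vein tree: (image uint8, mask uint8 {0,1}).

    image = background + illumination gradient - vein depth profile, then
    optical blur, sensor noise and a session pose jitter applied identically
    to image and mask.
    """
    h, w = tree.frame
    rng = _rng_for(session_seed, "scene")
    mask, centre = rasterize_tree(tree)

    # depth profile: a Gaussian cross-section of the distance to the
    # centreline, so the centreline is exactly the ridge minimum and
    # intensity rises monotonically towards (and slightly beyond) the wall
    if centre.any():
        d2c = ndi.distance_transform_edt(1 - centre)
        sigma_v = max(1.0, float(tree.radii.mean()) * 0.8)
        profile = np.exp(-(d2c ** 2) / (2.0 * sigma_v ** 2))
    else:
        profile = np.zeros_like(mask, dtype=float)
    theta = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[0:h, 0:w]
    gradient = params.gradient_amp * (np.cos(theta) * (cc / w - 0.5)
                                      + np.sin(theta) * (rr / h - 0.5)) * 2.0
    img = params.background_level + gradient - params.vein_contrast * profile
    if params.blur_sigma > 0:
        img = ndi.gaussian_filter(img, params.blur_sigma)
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)

    rot, trans, scale = session_jitter_params(params, session_seed)
    if rot != 0.0 or trans != (0.0, 0.0) or scale != 1.0:
        img = apply_affine(img, rot, trans, scale, binary=False)
        mask = apply_affine(mask, rot, trans, scale, binary=True).astype(np.uint8)

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, mask.astype(np.uint8)


def _session_seed(root_seed: int, spec: SubjectSpec, session: int) -> int:
    words = _stable_hash(root_seed, spec.subject_id, spec.wrist, session)
    mix = 0
    for wd in words:
        mix = zlib.crc32(int(wd).to_bytes(8, "little"), mix)
    return int(mix) & 0x7FFFFFFF


def generate_dataset(n_subjects: int, n_sessions: int = 2, seed: int = 0,
                     params: SceneParams | None = None, frame: tuple = (256, 256)):
    """Full in-memory dataset: (registry DataFrame, images, masks).

    Pure function of its arguments; rows of the registry align with the image
    and mask lists.
    """
    params = params or SceneParams()
    registry = make_registry(n_subjects, n_sessions, seed)
    images, masks = [], []
    trees: dict = {}
    for row in registry.itertuples():
        key = (row.subject_id, row.wrist)
        if key not in trees:
            spec = SubjectSpec(row.subject_id, row.wrist, seed, n_sessions)
            trees[key] = (spec, grow_vein_tree(spec, frame))
        spec, tree = trees[key]
        img, mask = render_session(tree, params, _session_seed(seed, spec, row.session))
        images.append(img)
        masks.append(mask)
    return registry, images, masks


def save_dataset(root, registry: pd.DataFrame, images, masks) -> pd.DataFrame:
    """Write images/masks as 8-bit grayscale PNGs plus registry.csv.

    Layout: <root>/<subject_id>/<wrist>/<session>.png with a mirrored
    <root>/masks/... hierarchy; masks stored as {0, 255}.
    """
    import imageio.v3 as iio
    from pathlib import Path

    root = Path(root)
    registry = registry.copy()
    for i, row in enumerate(registry.itertuples()):
        img_path = root / row.subject_id / row.wrist / f"{row.session}.png"
        mask_path = root / "masks" / row.subject_id / row.wrist / f"{row.session}.png"
        img_path.parent.mkdir(parents=True, exist_ok=True)
        mask_path.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(img_path, images[i])
        iio.imwrite(mask_path, (masks[i] * 255).astype(np.uint8))
        registry.loc[registry.index[i], "image_path"] = str(img_path)
        registry.loc[registry.index[i], "mask_path"] = str(mask_path)
    registry.to_csv(root / "registry.csv", index=False)
    return registry
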