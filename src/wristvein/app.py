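"""End-to-end orchestration: enrolment, verification and identification.

The operational flow mirrors the recognition pipeline: preprocess the raw
capture, segment it to a binary vein mask with the trained U-Net, then
either store the mask / its 128-d embedding as an enrolled template
(enrolment), compare the probe against one claimed identity (verification,
1:1) or rank it against the whole gallery (identification, 1:N).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import preprocess as pp
from . import unet as unet_mod
from .matcher_cnn import CnnMatcher, CnnMatcherConfig, match_probability_cnn
from .matcher_siamese import (SiameseConfig, SiameseEmbedding, decide,
                              embed_batch, euclidean_distance)
from .preprocess import PreprocessConfig
from .training import load_weights
from .unet import UNet, UNetConfig

log = logging.getLogger(__name__)

# shell-friendly exit codes: pipelines can branch on the decision
EXIT_MATCH, EXIT_NO_MATCH, EXIT_ERROR = 0, 1, 2


class MissingModelError(RuntimeError):
    pass


def load_model(path):
    """Load any checkpoint written by :func:`wristvein.training.save_model`,
    dispatching on the JSON sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists() or not path.with_suffix(".npz").exists():
        raise MissingModelError(
            f"no checkpoint at {path}; train one with `wristvein train-unet` "
            "or `wristvein train-matcher`")
    cfg = json.loads(sidecar.read_text())
    kind = cfg.pop("model")
    cfg = {k: _detuple(v) for k, v in cfg.items()}
    if kind == "unet":
        gab = cfg.pop("gabor")
        model = UNet(UNetConfig(gabor=unet_mod.GaborParams(**gab), **cfg))
    elif kind == "cnn_matcher":
        model = CnnMatcher(CnnMatcherConfig(**cfg))
    elif kind == "siamese":
        model = SiameseEmbedding(SiameseConfig(**cfg))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    load_weights(model, path)
    return model


def _detuple(v):
    if isinstance(v, list):
        return tuple(tuple(e) if isinstance(e, list) else e for e in v)
    return v


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio
    try:
        img = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    return pp.as_gray_u8(img)


def probe_to_mask(img: np.ndarray, segmenter: UNet,
                  pre_cfg: PreprocessConfig | None = None) -> np.ndarray:
    cfg = pre_cfg or PreprocessConfig(target_size=tuple(segmenter.cfg.input_size))
    enhanced = pp.preprocess_pipeline(img, cfg)
    return unet_mod.segment(segmenter, enhanced)


@dataclass
class Template:
    template_id: str
    subject_id: str
    kind: str              # "siamese" (embedding) or "cnn" (stored mask)
    payload_path: str


class TemplateStore:
    """Directory-backed gallery: one subdirectory per subject, JSON index.

    Siamese templates are 128-float CSV vectors; CNN templates are the
    enrolled masks themselves (CSV rasters of {0,1})."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.index_path = self.root / "index.json"
        self.index = (json.loads(self.index_path.read_text())
                      if self.index_path.exists() else [])

    def _save_index(self):
        self.index_path.write_text(json.dumps(self.index, indent=2))

    def add(self, subject_id: str, kind: str, payload: np.ndarray) -> Template:
        n = sum(1 for t in self.index if t["subject_id"] == subject_id)
        tid = f"{subject_id}-{n:03d}"
        subdir = self.root / subject_id
        subdir.mkdir(exist_ok=True)
        path = subdir / f"{tid}.csv"
        np.savetxt(path, np.atleast_2d(payload), fmt="%.8g", delimiter=",")
        t = Template(tid, subject_id, kind, str(path))
        self.index.append(t.__dict__)
        self._save_index()
        return t

    def templates(self, subject_id: str | None = None):
        for t in self.index:
            if subject_id is None or t["subject_id"] == subject_id:
                yield Template(**t), np.loadtxt(t["payload_path"], delimiter=",", ndmin=2)

    def subjects(self):
        return sorted({t["subject_id"] for t in self.index})


def enroll(image, subject_id: str, store: TemplateStore, segmenter: UNet,
           matcher, pre_cfg: PreprocessConfig | None = None) -> Template:
    """Preprocess -> segment -> (embed | store mask) -> persist."""
    img = read_image(image) if isinstance(image, (str, Path)) else pp.as_gray_u8(image)
    mask = probe_to_mask(img, segmenter, pre_cfg)
    if isinstance(matcher, SiameseEmbedding):
        size = tuple(matcher.cfg.input_size)
        m = pp.resize(mask, size, binary=True)
        vec = embed_batch(matcher, m[None])[0]
        return store.add(subject_id, "siamese", vec)
    size = tuple(matcher.cfg.input_size)
    m = pp.resize(mask, size, binary=True)
    return store.add(subject_id, "cnn", m.astype(np.uint8))


def _score_against(matcher, probe_mask: np.ndarray, payload: np.ndarray):
    """Return (distance_or_score, accept_metric) for one template.

    For the Siamese matcher the comparison value is a Euclidean distance
    (smaller = better); for the CNN it is a match probability (larger =
    better)."""
    if isinstance(matcher, SiameseEmbedding):
        size = tuple(matcher.cfg.input_size)
        m = pp.resize(probe_mask, size, binary=True)
        e = embed_batch(matcher, m[None])[0]
        return float(euclidean_distance(e, payload.ravel()))
    size = tuple(matcher.cfg.input_size)
    m = pp.resize(probe_mask, size, binary=True)
    return float(match_probability_cnn(matcher, m.astype(np.float32),
                                       payload.astype(np.float32)))


def verify(image, claimed_id: str, store: TemplateStore, segmenter: UNet,
           matcher, tau: float, pre_cfg: PreprocessConfig | None = None):
    """1:1 verification of a claimed identity; returns a MatchDecision-like
    record (for the CNN the 'distance' is 1 - probability)."""
    if claimed_id not in store.subjects():
        raise KeyError(f"unknown subject {claimed_id!r}; enroll first")
    img = read_image(image) if isinstance(image, (str, Path)) else pp.as_gray_u8(image)
    probe = probe_to_mask(img, segmenter, pre_cfg)
    best = None
    for _t, payload in store.templates(claimed_id):
        v = _score_against(matcher, probe, payload)
        d = v if isinstance(matcher, SiameseEmbedding) else 1.0 - v
        if best is None or d < best:
            best = d
    return decide(best, tau)


def identify(image, store: TemplateStore, segmenter: UNet, matcher,
             tau: float, pre_cfg: PreprocessConfig | None = None):
    """1:N identification: subjects ranked best-first; the top hit is
    accepted only if it passes the threshold."""
    if not store.subjects():
        raise ValueError("empty gallery; enroll subjects first")
    img = read_image(image) if isinstance(image, (str, Path)) else pp.as_gray_u8(image)
    probe = probe_to_mask(img, segmenter, pre_cfg)
    ranking = []
    for sid in store.subjects():
        ds = [(_score_against(matcher, probe, payload))
              for _t, payload in store.templates(sid)]
        if isinstance(matcher, SiameseEmbedding):
            d = min(ds)
        else:
            d = 1.0 - max(ds)
        ranking.append((sid, d))
    ranking.sort(key=lambda t: t[1])
    top_sid, top_d = ranking[0]
    return ranking, decide(top_d, tau), top_sid
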