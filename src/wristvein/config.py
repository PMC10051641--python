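"""Application configuration: one YAML file exposing every hyperparameter.

Nested dataclass configs (preprocess, labeling, U-Net, matchers,
augmentation) round-trip losslessly through YAML; tuples are serialised as
lists and restored on load.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .labeling import LabelingConfig
from .matcher_cnn import CnnMatcherConfig
from .matcher_siamese import SiameseConfig
from .pairing import AugmentConfig
from .preprocess import PreprocessConfig
from .unet import UNetConfig


@dataclass(frozen=True)
class AppConfig:
    data_root: str = "data"
    model_dir: str = "models"
    template_store: str = "templates"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    cnn: CnnMatcherConfig = field(default_factory=CnnMatcherConfig)
    siamese: SiameseConfig = field(default_factory=SiameseConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)


def _restore(cls, data):
    """Rebuild a (possibly nested) dataclass from plain YAML data,
    converting lists back to tuples where the default was a tuple."""
    kwargs = {}
    defaults = cls()
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        current = getattr(defaults, f.name)
        if is_dataclass(current) and isinstance(v, dict):
            v = _restore(type(current), v)
        elif isinstance(current, tuple) and isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        kwargs[f.name] = v
    return cls(**kwargs)


def to_yaml(cfg: AppConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def from_yaml(path) -> AppConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _restore(AppConfig, data)
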