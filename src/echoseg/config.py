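"""Run configuration: YAML loading, flag overrides and provenance tracking.

A :class:`RunConfig` is the merged view of the training, backbone, loss and
augmentation settings. Every field has a default; values can come from a
YAML file (sections ``train:``, ``model:``, ``loss:``, ``augment:``) and be
overridden by CLI flags, with precedence flag > file > default. The source
of every field is recorded so the many unstated hyperparameters of the
method stay auditable, and the fully resolved config is serialised next to
each output artifact; re-loading that snapshot reproduces the run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .losses import DCLossConfig
from .model import BackboneConfig
from .training import TrainConfig


class ValidationError(ValueError):
    pass


_SECTIONS = {"train": TrainConfig, "model": BackboneConfig,
             "loss": DCLossConfig, "augment": AugmentConfig}
# TrainConfig fields that are themselves dataclasses handled as sections
_NESTED = {"backbone": "model", "loss": "loss", "augment": "augment"}


@dataclass
class RunConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    provenance: dict = field(default_factory=dict)

    @property
    def model(self) -> BackboneConfig:
        return self.train.backbone

    @property
    def loss(self) -> DCLossConfig:
        return self.train.loss

    @property
    def augment(self) -> AugmentConfig:
        return self.train.augment

    def to_dict(self) -> dict:
        out = {"train": {}, "model": self.model.to_dict(),
               "loss": dataclasses.asdict(self.loss),
               "augment": dataclasses.asdict(self.augment)}
        for f in dataclasses.fields(TrainConfig):
            if f.name in _NESTED:
                continue
            out["train"][f.name] = getattr(self.train, f.name)
        for section in ("model", "loss", "augment"):
            for key, value in out[section].items():
                if isinstance(value, tuple):
                    out[section][key] = list(value)
        return out

    def save(self, path) -> None:
        snapshot = self.to_dict()
        snapshot["provenance"] = dict(self.provenance)
        Path(path).write_text(yaml.safe_dump(snapshot, sort_keys=True))


def _coerce(section_cls, key, value):
    for f in dataclasses.fields(section_cls):
        if f.name == key:
            return value
    raise ValidationError(
        f"unknown option {key!r} for section {section_cls.__name__}")


def load_config(path=None, overrides: dict | None = None,
                preset: str | None = None) -> RunConfig:
    """Build a resolved RunConfig from defaults, an optional YAML file and
    flat dotted overrides such as ``{"train.seed": 7, "loss.temperature": 0.2}``.
    """
    values: dict[str, dict] = {name: {} for name in _SECTIONS}
    provenance: dict[str, str] = {}

    if preset == "tiny":
        for key, val in dataclasses.asdict(BackboneConfig.tiny()).items():
            values["model"][key] = val
            provenance[f"model.{key}"] = "preset:tiny"

    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} must map sections")
        raw.pop("provenance", None)
        for section, entries in raw.items():
            if section not in _SECTIONS:
                raise ValidationError(f"unknown config section {section!r}")
            for key, val in (entries or {}).items():
                _coerce(_SECTIONS[section], key, val)
                values[section][key] = val
                provenance[f"{section}.{key}"] = f"file:{path}"

    for dotted, val in (overrides or {}).items():
        if val is None:
            continue
        section, _, key = dotted.partition(".")
        if section not in _SECTIONS:
            raise ValidationError(f"unknown config section in {dotted!r}")
        _coerce(_SECTIONS[section], key, val)
        values[section][key] = val
        provenance[dotted] = "flag"

    for section, cls in _SECTIONS.items():
        for f in dataclasses.fields(cls):
            if section == "train" and f.name in _NESTED:
                continue
            provenance.setdefault(f"{section}.{f.name}", "default")

    backbone = BackboneConfig(**values["model"])
    loss = DCLossConfig(**values["loss"])
    augment = AugmentConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in values["augment"].items()})
    train_kwargs = dict(values["train"])
    for nested in _NESTED:
        train_kwargs.pop(nested, None)
    train = TrainConfig(backbone=backbone, loss=loss, augment=augment,
                        **train_kwargs)
    return RunConfig(train=train, provenance=provenance)
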