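"""Pipeline configuration: nested, strict, YAML round-trippable.

``PipelineConfig`` groups the per-stage settings objects.  Loading is
strict — unknown keys are rejected — and ``to_dict``/``from_dict`` are
exact inverses, so a loaded config re-serializes identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluate import SplitSpec
from .features import FeatureParams
from .ml import MLConfig
from .preprocess import SegmentationConfig
from .rules import RuleThresholds
from .synth import GeneratorParams

__all__ = ["PipelineConfig", "config_fingerprint"]

_SECTIONS = {
    "generator": GeneratorParams,
    "segmentation": SegmentationConfig,
    "features": FeatureParams,
    "rules": RuleThresholds,
    "ml": MLConfig,
    "split": SplitSpec,
}


def _to_plain(value):
    if isinstance(value, tuple):
        return [_to_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _to_plain(v) for k, v in value.items()}
    return value


def _from_plain(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        default = f.default if f.default is not dataclasses.MISSING else None
        if isinstance(value, list) and (
            isinstance(default, tuple) or "tuple" in str(f.type)
        ):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        if key == "cycle_duration" and isinstance(value, dict):
            value = {k: tuple(v) for k, v in value.items()}
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureParams = field(default_factory=FeatureParams)
    rules: RuleThresholds = field(default_factory=RuleThresholds)
    ml: MLConfig = field(default_factory=MLConfig)
    split: SplitSpec = field(default_factory=SplitSpec)

    def to_dict(self) -> dict:
        return {
            name: _to_plain(dataclasses.asdict(getattr(self, name)))
            for name in _SECTIONS
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {
            name: _from_plain(section_cls, data[name])
            for name, section_cls in _SECTIONS.items()
            if name in data
        }
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


def config_fingerprint(config: PipelineConfig) -> str:
    """Short stable hash identifying a configuration."""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12]
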