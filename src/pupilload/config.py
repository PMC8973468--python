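"""YAML pipeline configuration with strict (unknown-key-rejecting) parsing."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .preprocess import PreprocessConfig
from .stats import StatsConfig
from .synthetic_data import GeneratorConfig


class ConfigError(ValueError):
    pass


@dataclass
class ClassifyConfig:
    k: int = 5
    families: tuple = (
        "svm_linear",
        "svm_rbf",
        "svm_sigmoid",
        "linear_svc",
        "lda",
        "decision_tree",
        "random_forest",
    )
    group_by_subject: bool = False


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, in one validated object."""

    seed: int = 0
    out_dir: str = "results/run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, mapping: dict, path: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        v = mapping[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in _SECTIONS:
            v = _build(_SECTIONS[f.name], v, f"{path}.{f.name}")
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTIONS = {
    "generator": GeneratorConfig,
    "preprocess": PreprocessConfig,
    "features": FeatureConfig,
    "stats": StatsConfig,
    "classify": ClassifyConfig,
}


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = _build(PipelineConfig, raw, "config")
    cfg.generator.validate()
    return cfg


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
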