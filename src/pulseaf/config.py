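"""Pipeline configuration: one JSON document covering every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = ["PipelineConfig", "GeneratorConfig", "ClassifierConfig", "EvaluationConfig"]


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                v = _from_dict(_NESTED[f.name], v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class GeneratorConfig:
    """Synthetic-dataset composition and per-class generator parameters."""

    n_afib: int = 1000
    n_sinus: int = 500
    n_pc_bigeminy: int = 250
    n_pc_random: int = 250
    mean_interval: float = 0.75
    afib_cv: float = 0.13
    sinus_jitter_sd: float = 0.02
    pc_coupling_fraction: float = 0.7
    pc_probability: float = 0.2
    n_intervals_mean: float = 22.0
    n_intervals_sd: float = 3.0
    min_intervals: int = 10


@dataclass
class FeatureSettings:
    gap_threshold: float | None = None
    relative_gap: float = 0.12
    min_intervals: int = 10


@dataclass
class ClassifierConfig:
    rounds: int = 50
    max_depth: int = 2


@dataclass
class EvaluationConfig:
    confidence: float = 0.95
    mcnemar_method: str = "exact_binomial"


_NESTED: dict[str, type] = {}


@dataclass
class PipelineConfig:
    """Complete, JSON-round-trippable configuration with full defaults."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


_NESTED.update({
    "generator": GeneratorConfig,
    "features": FeatureSettings,
    "classifier": ClassifierConfig,
    "evaluation": EvaluationConfig,
})
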