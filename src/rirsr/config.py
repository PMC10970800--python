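"""Composite run configuration with strict plain-text round-tripping.

A run is described by one YAML file with sections ``phantom``,
``degradation``, ``model``, ``train``, ``metrics``, ``paths`` and a
global ``seed``.  Every key of every hyperparameter is explicit and
versionable; unknown keys are errors, not warnings, and loading then
dumping then loading again reproduces the configuration exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .degrade import DegradationSpec
from .metrics import SSIMParams
from .model import ModelConfig
from .phantom import PhantomSpec
from .train import TrainConfig

__all__ = ["RunConfig"]

_SECTIONS = {
    "phantom": PhantomSpec,
    "degradation": DegradationSpec,
    "model": ModelConfig,
    "train": TrainConfig,
    "metrics": SSIMParams,
}


@dataclass(frozen=True)
class RunConfig:
    """All parameters of one end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    degradation: DegradationSpec = field(default_factory=lambda: DegradationSpec(scale=4))
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: SSIMParams = field(default_factory=SSIMParams)
    paths: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model.scale != self.degradation.scale:
            raise ValueError(
                f"model scale {self.model.scale} != degradation scale "
                f"{self.degradation.scale}"
            )

    def to_dict(self) -> dict:
        out = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        out["paths"] = dict(self.paths)
        out["seed"] = self.seed
        # YAML cannot round-trip tuples; store scale weights as a list.
        if out["metrics"]["scale_weights"] is not None:
            out["metrics"]["scale_weights"] = list(out["metrics"]["scale_weights"])
        return out

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known_top = set(_SECTIONS) | {"paths", "seed"}
        unknown = set(data) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            section = dict(data.get(name, {}))
            valid = {f.name for f in fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ValueError(
                    f"unknown keys in section '{name}': {sorted(bad)}"
                )
            if name == "metrics" and section.get("scale_weights") is not None:
                section["scale_weights"] = tuple(section["scale_weights"])
            kwargs[name] = section_cls(**section)
        kwargs["paths"] = dict(data.get("paths", {}))
        kwargs["seed"] = int(data.get("seed", 0))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)
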