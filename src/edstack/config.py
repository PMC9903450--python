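"""Run configuration: a single validated mapping driving the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from edstack.models import HyperParams
from edstack.synthetic import GeneratorConfig


@dataclass
class CVConfig:
    repeats: int = 5
    folds: int = 5

    def validate(self) -> None:
        if self.repeats < 1 or self.folds < 2:
            raise ValueError("cv needs repeats >= 1 and folds >= 2")


@dataclass
class ScenarioDefaults:
    uplift_fraction: float = 0.10
    ramp_step: float = 0.2
    horizon_years: int = 4


@dataclass
class RunConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    hp_capacity: HyperParams = field(default_factory=HyperParams)
    hp_health: HyperParams = field(default_factory=HyperParams)
    cv: CVConfig = field(default_factory=CVConfig)
    scenario: ScenarioDefaults = field(default_factory=ScenarioDefaults)
    input_dir: str | None = None  # None -> simulate inputs

    def validate(self) -> None:
        self.cv.validate()
        self.generator.validate()
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")

    def to_dict(self) -> dict:
        out = asdict(self)
        out["generator"]["population_range"] = list(
            out["generator"]["population_range"]
        )
        return out

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


_SECTIONS = {"seed", "generator", "hp_capacity", "hp_health", "cv", "scenario",
             "input_dir"}


def _build(cls, data: dict, section: str):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    if cls is GeneratorConfig and "population_range" in data:
        data = dict(data, population_range=tuple(data["population_range"]))
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    if path is None:
        cfg = RunConfig()
        cfg.validate()
        return cfg
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    cfg = RunConfig(
        seed=int(data.get("seed", 0)),
        generator=_build(GeneratorConfig, data.get("generator", {}), "generator"),
        hp_capacity=_build(HyperParams, data.get("hp_capacity", {}), "hp_capacity"),
        hp_health=_build(HyperParams, data.get("hp_health", {}), "hp_health"),
        cv=_build(CVConfig, data.get("cv", {}), "cv"),
        scenario=_build(ScenarioDefaults, data.get("scenario", {}), "scenario"),
        input_dir=data.get("input_dir"),
    )
    cfg.validate()
    return cfg
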