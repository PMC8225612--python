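"""Experiment configuration: validated, YAML/JSON round-trippable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .movement import FloodKernel, WalkParams
from .population import DemographyParams
from .synthetic_delta import DeltaScenario


class ConfigError(ValueError):
    """Raised with every violation found while loading a configuration."""


@dataclass
class SimConfig:
    scenario: DeltaScenario = field(default_factory=DeltaScenario)
    demography: DemographyParams = field(default_factory=DemographyParams)
    walk: WalkParams = field(default_factory=WalkParams)
    kernel: FloodKernel = field(default_factory=FloodKernel)
    n_realizations: int = 30
    base_seed: int = 0
    initial_occupancy: float = 0.5   # founders as a fraction of year-one capacity
    initial_females: int | None = None  # overrides initial_occupancy when set
    n_sites: int = 4
    sample_per_site: int = 30
    settle_threshold: float = 0.1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        errors: list[str] = []
        kwargs: dict = {}
        sections = {
            "scenario": DeltaScenario,
            "demography": DemographyParams,
            "walk": WalkParams,
            "kernel": FloodKernel,
        }
        for name, typ in sections.items():
            try:
                sub = d.get(name, {})
                if isinstance(sub, dict):
                    for k, v in sub.items():
                        if isinstance(v, list):
                            sub[k] = tuple(v)
                    kwargs[name] = typ(**sub)
                else:
                    kwargs[name] = sub
            except (TypeError, ValueError) as e:
                errors.append(f"{name}: {e}")
        scalar_fields = {
            f.name for f in dataclasses.fields(cls) if f.name not in sections
        }
        for k, v in d.items():
            if k in sections:
                continue
            if k not in scalar_fields:
                errors.append(f"unknown configuration key {k!r}")
            else:
                kwargs[k] = v
        if errors:
            raise ConfigError("; ".join(errors))
        cfg = cls(**kwargs)
        more = cfg.validate()
        if more:
            raise ConfigError("; ".join(more))
        return cfg

    def validate(self) -> list[str]:
        errors = []
        if self.n_realizations < 1:
            errors.append("n_realizations must be >= 1")
        if not 0.0 <= self.initial_occupancy <= 1.0:
            errors.append("initial_occupancy must be in [0, 1]")
        if self.initial_females is not None and self.initial_females < 0:
            errors.append("initial_females must be non-negative")
        return errors

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
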