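"""Declarative scenario configuration.

A :class:`ScenarioConfig` fully parameterizes one experiment cell:
population, environment, behavior gates, metabolic constants, the app
engagement triple (or none for the no-app counterfactual), attrition,
the baseline probability to exercise, horizon, replicate count and
master seed.  Configs round-trip through plain dicts and YAML files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .app import AttritionParams, EngagementTriple
from .behavior import GateParams
from .environment import EnvironmentSpec
from .metabolism import MetabolicParams
from .population import PopulationSpec

__all__ = ["ScenarioConfig", "load_config", "save_config"]

#: 52 exact weeks per simulated year keeps minutes-per-week aggregation exact
DAYS_PER_YEAR = 364


def _tuplify(value):
    return tuple(value) if isinstance(value, list) else value


def _build(cls, data):
    if data is None:
        return None
    if isinstance(data, cls):
        return data
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**{k: _tuplify(v) for k, v in data.items()})


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one simulation scenario."""

    population: PopulationSpec = field(default_factory=PopulationSpec)
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    gates: GateParams = field(default_factory=GateParams)
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    engagement: EngagementTriple | None = None
    engagement_mode: str = "sampled"
    attrition: AttritionParams = field(default_factory=AttritionParams)
    app_intro_day: int = 0
    baseline_exercise_prob: float = 0.25
    horizon_years: int = 5
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_exercise_prob <= 1.0:
            raise ValueError("baseline_exercise_prob must be a probability")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        if self.engagement_mode not in ("sampled", "expected"):
            raise ValueError("engagement_mode must be 'sampled' or 'expected'")
        if self.app_intro_day < 0:
            raise ValueError("app_intro_day must be non-negative")

    @property
    def horizon_days(self) -> int:
        return self.horizon_years * DAYS_PER_YEAR

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    def without_app(self) -> "ScenarioConfig":
        """The paired no-app counterfactual (same population and seed)."""
        return self.replace(engagement=None)

    def to_dict(self) -> dict:
        def encode(value):
            if is_dataclass(value) and not isinstance(value, type):
                return {f.name: encode(getattr(value, f.name)) for f in fields(value)}
            if isinstance(value, tuple):
                return list(value)
            return value

        return encode(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        nested = {
            "population": PopulationSpec,
            "environment": EnvironmentSpec,
            "gates": GateParams,
            "metabolic": MetabolicParams,
            "engagement": EngagementTriple,
            "attrition": AttritionParams,
        }
        kwargs = {}
        for key, value in data.items():
            if key in nested:
                kwargs[key] = _build(nested[key], value)
            else:
                kwargs[key] = value
        unknown = set(kwargs) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown ScenarioConfig fields: {sorted(unknown)}")
        return cls(**kwargs)


def load_config(path) -> ScenarioConfig:
    """Read a scenario from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path) -> None:
    """Write a scenario to a YAML file."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
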