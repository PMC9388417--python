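"""Run configuration: schema validation and provenance for reproducible runs.

A :class:`RunConfig` selects either a battery or a single condition, may
override a restricted set of scenario parameters, and pins a base seed.
Unknown keys are rejected, and the resolved configuration is echoed into the
output directory so every artifact is traceable to a config hash plus seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .environments import CONDITIONS, Condition
from .experiments import BATTERIES

#: overridable scenario parameters, with bounds where they apply
_PROBABILITY_KEYS = {"rho_agent", "rho_true", "p_changeup_true", "q_hit"}
_POSITIVE_KEYS = {"eta", "a_strength", "r_early", "r_late", "reward", "loss",
                  "persistence"}
_OTHER_KEYS = {"gamma", "learn_context", "learn_cue", "action_mode",
               "cue_congruent", "forced_cue"}
ALLOWED_OVERRIDES = _PROBABILITY_KEYS | _POSITIVE_KEYS | _OTHER_KEYS


class RunConfig(BaseModel):
    """Validated configuration for one reproducible run."""

    model_config = ConfigDict(extra="forbid")

    battery: str | None = None
    condition: str | None = None
    observers: int | None = Field(default=None, ge=1)
    trials: int | None = Field(default=None, ge=1)
    seed: int = 0
    out: Path = Path("results")
    verbosity: int = Field(default=1, ge=0, le=2)
    overrides: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _one_selector(self) -> "RunConfig":
        if (self.battery is None) == (self.condition is None):
            raise ValueError("specify exactly one of 'battery' or 'condition'")
        if self.battery is not None and self.battery not in BATTERIES:
            raise ValueError(
                f"unknown battery {self.battery!r}; known: {sorted(BATTERIES)}"
            )
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; known: {sorted(CONDITIONS)}"
            )
        return self

    @field_validator("overrides")
    @classmethod
    def _check_overrides(cls, overrides: dict[str, Any]) -> dict[str, Any]:
        for key, value in overrides.items():
            if key not in ALLOWED_OVERRIDES:
                raise ValueError(
                    f"unknown override key {key!r}; allowed: {sorted(ALLOWED_OVERRIDES)}"
                )
            if key in _PROBABILITY_KEYS:
                v = float(value)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{key} must lie in [0, 1], got {value}")
            if key in _POSITIVE_KEYS and float(value) <= 0:
                raise ValueError(f"{key} must be positive, got {value}")
        return overrides

    # -- provenance ---------------------------------------------------------
    def canonical_json(self) -> str:
        payload = self.model_dump(mode="json")
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return RunConfig(**data)


def apply_overrides(condition: Condition, overrides: dict[str, Any]) -> Condition:
    """Return a condition copy with the overridable parameters replaced.

    Keys are applied to whichever of the environment spec or the agent
    parameters defines them; a key neither defines is an error.
    """
    spec = condition.spec
    agent = condition.agent
    for key, value in overrides.items():
        if key in {f.name for f in dataclasses.fields(spec)}:
            spec = dataclasses.replace(spec, **{key: _coerce(spec, key, value)})
        elif key in {f.name for f in dataclasses.fields(agent)}:
            agent = dataclasses.replace(agent, **{key: _coerce(agent, key, value)})
        else:
            raise ValueError(
                f"override {key!r} does not apply to condition {condition.name!r}"
            )
    return dataclasses.replace(condition, spec=spec, agent=agent)


def _coerce(obj: Any, key: str, value: Any) -> Any:
    current = getattr(obj, key)
    if isinstance(current, bool):
        if isinstance(value, str):
            return value.lower() in {"1", "true", "yes", "on"}
        return bool(value)
    if isinstance(current, float):
        return float(value)
    return value
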