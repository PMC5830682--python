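"""YAML configuration for scenarios and constants.

The file dialect is YAML with up to three top-level sections::

    arena:        # ArenaConfig fields
      n_flab: 10
      n_hermi: 3
    scenario:     # ScenarioConfig fields other than the arena
      n_steps: 150000
      n_trials: 6
      learning_enabled: true
      satiation_enabled: true
    constants:    # any Constants overrides
      k6: 20.0

Missing sections/fields fall back to package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .arena import ArenaConfig
from .constants import DEFAULT_CONSTANTS, Constants
from .experiments import ScenarioConfig


def load_config(path: str | Path) -> tuple[ScenarioConfig, Constants]:
    """Parse a YAML config file into (ScenarioConfig, Constants)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - {"arena", "scenario", "constants"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    arena = ArenaConfig.from_dict(raw.get("arena", {}))
    constants = DEFAULT_CONSTANTS.replace(**(raw.get("constants", {}) or {}))
    scenario_kw = dict(raw.get("scenario", {}) or {})
    scenario = ScenarioConfig(arena=arena, **scenario_kw)
    return scenario, constants


def dump_constants(constants: Constants) -> str:
    """Constants rendered as a YAML fragment (the --dump-constants output)."""
    return yaml.safe_dump({"constants": constants.to_dict()}, sort_keys=False)
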