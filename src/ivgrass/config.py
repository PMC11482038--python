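"""Plain-text (YAML) run configuration.

A config file holds optional sections -- ``stand``, ``environment``,
``constants``, ``harvest``, ``mortality`` -- whose keys map onto
:class:`~ivgrass.simulator.SimConfig` fields, plus an optional ``traits``
section serialising the reference :class:`~ivgrass.traits.TraitSpec`.
Sections exist for readability only; keys are flattened before use and
unknown keys raise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .simulator import SimConfig
from .traits import TraitSpec

__all__ = ["load_config", "dump_config"]

SECTIONS = ("stand", "environment", "constants", "harvest", "mortality")


def load_config(path) -> tuple:
    """Read a YAML run config; returns (SimConfig, TraitSpec or None)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    flat = {}
    for key, value in raw.items():
        if key == "traits":
            continue
        if key in SECTIONS and isinstance(value, dict):
            flat.update(value)
        else:
            flat[key] = value
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(flat) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "harvest_days" in flat:
        flat["harvest_days"] = tuple(flat["harvest_days"])
    sim = SimConfig(**flat)
    spec = TraitSpec.from_dict(raw["traits"]) if "traits" in raw else None
    return sim, spec


def dump_config(sim: SimConfig, spec: TraitSpec | None = None) -> str:
    """Serialise a SimConfig (and optional TraitSpec) back to YAML."""
    payload = dataclasses.asdict(sim)
    payload["harvest_days"] = list(payload["harvest_days"])
    if spec is not None:
        payload = {"constants": payload, "traits": spec.to_dict()}
    return yaml.safe_dump(payload, sort_keys=False)
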