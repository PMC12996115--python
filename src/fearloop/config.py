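"""TOML/YAML configuration loading for the command-line tools.

A config file may carry a ``participant`` table (simulator physiology), a
``controller`` table (margins, iterations, exposure length) and a
``features`` table (bands, FAA pairs). All keys are optional; defaults come
from the library.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields
from pathlib import Path

import yaml

from .simulator import ParticipantParams

__all__ = ["load_config", "participant_from_config"]


def load_config(path) -> dict:
    path = Path(path)
    if path.suffix == ".toml":
        return tomllib.loads(path.read_text())
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(path.read_text()) or {}
    raise ValueError(f"unsupported config format: {path.suffix}")


def participant_from_config(cfg: dict) -> ParticipantParams:
    table = cfg.get("participant", {})
    valid = {f.name for f in fields(ParticipantParams)}
    unknown = set(table) - valid
    if unknown:
        raise ValueError(f"unknown participant keys: {sorted(unknown)}")
    return ParticipantParams(**table)
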