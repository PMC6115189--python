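"""Regime presets (parameter documents emulating the experimental conditions)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from ..errors import ConfigurationError
from ..synthetic_tissue import SimConfig

PRESET_NAMES = ("control", "xdd1_like", "pk2dpdl_like")


def preset_path(name: str) -> Path:
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return Path(str(resources.files(__package__) / f"{name}.yaml"))


def load_preset(name: str, **overrides) -> SimConfig:
    """SimConfig for one named regime, with optional field overrides."""
    doc = yaml.safe_load(preset_path(name).read_text()) or {}
    doc.update(overrides)
    return SimConfig(**doc)
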