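"""Bundled scenario presets (the bench study's experiment matrix)."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .config import RunConfig, parse_config

__all__ = ["list_presets", "load_preset", "preset_path"]


def _preset_dir():
    return resources.files(__package__) / "presets"


def list_presets() -> list[str]:
    """Names of the bundled presets."""
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _preset_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def preset_path(name: str) -> Path:
    p = _preset_dir() / f"{name}.yaml"
    if not p.is_file():
        raise KeyError(
            f"no preset {name!r}; available: {', '.join(list_presets())}"
        )
    return Path(str(p))


def load_preset(name: str) -> RunConfig:
    """Load a bundled preset by name (e.g. ``exp2_feasibility``)."""
    return parse_config(yaml.safe_load(preset_path(name).read_text()))
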