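"""Analysis configuration: packaged defaults plus user YAML overrides."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml


def _package_default() -> dict[str, Any]:
    text = resources.files("kellvar.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    merged = dict(base)
    for key, value in override.items():
        if key in merged and isinstance(merged[key], dict) and isinstance(value, Mapping):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, overlaid with a user YAML file."""
    cfg = _package_default()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def data_path(name: str) -> Path:
    """Path to a packaged data file (tables, property scales)."""
    return Path(str(resources.files("kellvar.data").joinpath(name)))
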