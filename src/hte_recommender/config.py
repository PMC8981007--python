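"""Run configuration: program constants and defaults loaded from YAML.

Every constant that defines the analysis (the ADAG conversion, the
eligibility cutoffs, the Box of engagement thresholds, the 65:35 split,
the 90-day engagement window) is read from ``defaults.yaml`` so that a
run is fully described by configuration plus a seed.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any

import yaml

CATEGORIES: tuple[str, ...] = (
    "coaching",
    "monitoring",
    "physical_activity",
    "nutrition",
    "content",
)
"""The five action categories, in the fixed tie-break order used everywhere."""


def _load_defaults() -> dict[str, Any]:
    text = resources.files("hte_recommender").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS = _load_defaults()


def default_config() -> dict[str, Any]:
    """A deep copy of the packaged default configuration tree."""
    return copy.deepcopy(_DEFAULTS)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict[str, Any]:
    """Load a run configuration: packaged defaults <- YAML file <- overrides."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        config = _deep_merge(config, user)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


# Convenience accessors for the two ADAG constants, used throughout.
ADAG_SLOPE: float = float(_DEFAULTS["adag"]["slope_mgdl_per_pct"])
ADAG_OFFSET: float = float(_DEFAULTS["adag"]["offset_mgdl"])
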