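"""Loading and overriding the bundled model-parameter configuration.

The default configuration (``thyret/data/parameters.yaml``) holds every
biokinetic parameter value and uncertainty distribution the models use.  A
user file with the same structure can override any subset of keys; mappings
are merged recursively, scalars and lists are replaced.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .distributions import DistributionSpec
from .errors import InvalidParameterError

__all__ = ["load_config", "default_config", "parse_distribution"]


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """The bundled default parameter configuration as a nested dict."""
    text = resources.files("thyret.data").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load the configuration, optionally merging a user override file."""
    config = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, Mapping):
            raise InvalidParameterError(f"config override {path} is not a mapping")
        config = _deep_merge(config, override)
    return config


def parse_distribution(entry: Any) -> DistributionSpec:
    """Turn a config entry into a :class:`DistributionSpec`.

    Accepts the mapping forms used in the YAML file, a bare number (treated
    as a fixed value) or an existing spec.
    """
    if isinstance(entry, DistributionSpec):
        return entry
    if isinstance(entry, (int, float)):
        return DistributionSpec.fixed(float(entry))
    if not isinstance(entry, Mapping) or "kind" not in entry:
        raise InvalidParameterError(f"malformed distribution entry: {entry!r}")
    kind = entry["kind"]
    try:
        if kind == "normal":
            return DistributionSpec.normal(entry["mean"], entry["sd"])
        if kind == "lognormal":
            return DistributionSpec.lognormal(entry["gm"], entry["gsd"])
        if kind == "triangular":
            return DistributionSpec.triangular(entry["min"], entry["mode"], entry["max"])
        if kind == "fixed":
            return DistributionSpec.fixed(entry["value"])
    except KeyError as exc:
        raise InvalidParameterError(f"distribution entry {entry!r} missing {exc}") from exc
    raise InvalidParameterError(f"unknown distribution kind {kind!r}")
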