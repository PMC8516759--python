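"""Run configuration: every tunable of the pipeline, loadable from YAML.

A config file is a flat YAML mapping; unknown keys are rejected so typos
fail loudly before any computation. All defaults are documented on
:class:`RunConfig` / :class:`~facegaze.aoi_geometry.AoiParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Union

import yaml

from .aoi_geometry import AoiParams

__all__ = ["ConfigError", "RunConfig", "load_run_config"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables.

    aoi
        AOI construction parameters (aspect ratios, margins, offsets, shape).
    confidence_threshold
        A keypoint counts as visible when its detector confidence is at or
        above this value (default 0.1).
    reid_max_distance
        Reject a re-identification when the nearest gallery entry is farther
        than this Euclidean distance; infinite by default (every detection
        gets the nearest identity).
    convention
        Duration-difference convention for agreement reports: ``net``
        (difference of face-gaze totals, default) or ``framewise`` (sum of
        mismatched frames).
    """

    aoi: AoiParams = field(default_factory=AoiParams)
    confidence_threshold: float = 0.1
    reid_max_distance: float = math.inf
    convention: str = "net"

    def __post_init__(self) -> None:
        if not 0 <= self.confidence_threshold <= 1:
            raise ConfigError("confidence_threshold must be in [0, 1]")
        if self.reid_max_distance < 0:
            raise ConfigError("reid_max_distance must be >= 0")
        if self.convention not in ("net", "framewise"):
            raise ConfigError("convention must be 'net' or 'framewise'")


_AOI_KEYS = {f.name for f in fields(AoiParams)}
_RUN_KEYS = {"confidence_threshold", "reid_max_distance", "convention"}


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Load a flat YAML config; missing keys keep their defaults."""
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _AOI_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    aoi_kwargs = {k: raw[k] for k in _AOI_KEYS & set(raw)}
    run_kwargs = {k: raw[k] for k in _RUN_KEYS & set(raw)}
    if run_kwargs.get("reid_max_distance") in ("inf", "unlimited", None):
        run_kwargs.pop("reid_max_distance", None)
    try:
        return RunConfig(aoi=AoiParams(**aoi_kwargs), **run_kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
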