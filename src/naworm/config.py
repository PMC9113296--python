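"""Run configuration: defaults, optional TOML config file, flag merging.

Precedence is command-line flags > config file > factory defaults, so a
run is fully reproducible from its config file plus its command line.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, Optional

from .pseudotorsion import DEFAULT_HELICAL_WINDOW, HelicalWindow

__all__ = ["RunConfig", "load_config"]

_ALLOWED_MODES = ("c4", "c1", "both")
_ALLOWED_AGGREGATORS = ("mean", "sum")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "both"
    helical_window: HelicalWindow = field(default=DEFAULT_HELICAL_WINDOW)
    aggregator: str = "mean"
    top_n: int = 20
    max_incomparable_fraction: float = 0.0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if self.mode not in _ALLOWED_MODES:
            raise ValueError(f"mode must be one of {_ALLOWED_MODES}")
        if self.aggregator not in _ALLOWED_AGGREGATORS:
            raise ValueError(f"aggregator must be one of {_ALLOWED_AGGREGATORS}")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if not (0.0 <= self.max_incomparable_fraction <= 1.0):
            raise ValueError("max_incomparable_fraction must lie in [0, 1]")


_WINDOW_KEYS = {
    "helical_eta_center": "eta_center",
    "helical_theta_center": "theta_center",
    "helical_eta_halfwidth": "eta_halfwidth",
    "helical_theta_halfwidth": "theta_halfwidth",
}
_SCALAR_KEYS = ("mode", "aggregator", "top_n", "max_incomparable_fraction", "log_level")


def load_config(
    path: Optional[str | Path] = None,
    overrides: Optional[Dict[str, Any]] = None,
) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus explicit overrides.

    ``overrides`` (typically parsed command-line flags) win over file values;
    ``None``-valued overrides are ignored.  Unknown keys in the file raise.
    """
    data: Dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        unknown = set(data) - set(_SCALAR_KEYS) - set(_WINDOW_KEYS)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})

    window_kwargs = {
        field_name: float(data.pop(key))
        for key, field_name in _WINDOW_KEYS.items()
        if key in data
    }
    cfg = RunConfig(**{k: data[k] for k in _SCALAR_KEYS if k in data})
    if window_kwargs:
        cfg = replace(
            cfg, helical_window=replace(DEFAULT_HELICAL_WINDOW, **window_kwargs)
        )
    return cfg
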