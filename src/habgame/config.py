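"""Run configuration: defaults, file loading, validation, round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import ModelError, derive_parameters


class ConfigError(ValueError):
    """Malformed or invalid configuration."""


@dataclass
class RunConfig:
    """Resolved settings for one run; serializes without loss."""

    params: dict = field(default_factory=dict)  # model-parameter overrides
    depth_max: float = 100.0
    n_nodes: int = 300
    tol: float = 1e-9
    h: float = 0.01
    t_end: float = 100.0
    mode: str = "optimal"
    N_c: float = 1.0
    N_p: float = 1.0
    sweep: str | None = None
    values: list[float] | None = None
    snapshot_stride: int = 10
    out: str = "runs"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        try:
            derive_parameters(self.params)
        except ModelError as err:
            raise ConfigError(str(err)) from err
        if self.n_nodes < 2:
            raise ConfigError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if self.depth_max <= 0:
            raise ConfigError(f"depth_max must be positive, "
                              f"got {self.depth_max}")
        if self.tol <= 0 or self.h <= 0 or self.t_end <= 0:
            raise ConfigError("tol, h and t_end must be positive")
        if self.mode not in ("optimal", "constant"):
            raise ConfigError(f"mode must be 'optimal' or 'constant', "
                              f"got {self.mode!r}")
        if self.sweep is not None and self.sweep not in ("K", "c"):
            raise ConfigError(f"sweep must be 'K' or 'c', got {self.sweep!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config file, merged over the defaults."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise ConfigError(f"cannot read config file {path}: {err}") from err
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse config file {path}: {err}") from err
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
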