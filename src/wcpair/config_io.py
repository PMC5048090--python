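"""Configuration parsing and result serialization.

Model configs are flat key-value documents (JSON or TOML) with the 14
keys ``a, b, c, d, e, w, alpha1, alpha2, beta1, beta2, I1, I2, J1, J2``.
All 14 must be present and numeric — defaults exist for integration
settings, never for model parameters.  Unknown keys are warned about and
ignored.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
import tomllib
from pathlib import Path

import numpy as np

from .model import ModelConfig, PARAM_KEYS

__all__ = ["parse_config", "write_config", "RunManifest", "dump_json"]

logger = logging.getLogger("wcpair")


def parse_config(path) -> ModelConfig:
    """Read a ModelConfig from a JSON or TOML file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise TypeError(f"config file {path} must contain a flat mapping")
    unknown = sorted(set(data) - set(PARAM_KEYS))
    if unknown:
        logger.warning("ignoring unknown config key(s): %s", ", ".join(unknown))
        data = {k: v for k, v in data.items() if k in PARAM_KEYS}
    return ModelConfig.from_dict(data)


def write_config(config: ModelConfig, path) -> None:
    """Write a ModelConfig as flat JSON (round-trips with parse_config)."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def dump_json(payload, path) -> None:
    """Write an analysis payload as JSON, converting numpy scalars/arrays."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2)
        fh.write("\n")


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record accompanying every output file.

    All commands are deterministic (fixed initial conditions and tangent
    frames, no random seeds), so re-running from a manifest reproduces the
    outputs bit-identically.
    """

    command: str
    config: dict
    settings: dict
    version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config: ModelConfig,
               settings: dict) -> "RunManifest":
        from . import __version__
        return cls(
            command=command,
            config=config.to_dict(),
            settings=_jsonable(settings),
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        dump_json(dataclasses.asdict(self), path)
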