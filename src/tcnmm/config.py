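"""Run configuration: model parameter overrides, drive and analysis
settings, round-tripping through YAML/JSON files."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import DriveSpec, ModelParameters

__all__ = ["RunConfig", "load_config"]

log = logging.getLogger("tcnmm")


@dataclass
class RunConfig:
    """Validated bundle of model, drive and analysis settings.

    Defaults reproduce the reference parameterization; an empty config
    file yields exactly the default model.
    """

    params: ModelParameters = field(default_factory=ModelParameters)
    drive: DriveSpec = field(default_factory=DriveSpec)
    duration: float = 60.0
    dt: float = 0.0039
    window: float = 2.0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.window <= 0 or self.window > self.duration:
            raise ValueError("window must be in (0, duration]")

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "drive": self.drive.to_dict(),
            "duration": self.duration,
            "dt": self.dt,
            "window": self.window,
            "out_dir": self.out_dir,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=1))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a mapping.  Model-parameter and drive symbols may
        appear flat at the top level (``c_tc_ei: 3.5``) or nested under
        ``params:`` / ``drive:``; unknown keys raise ValueError."""
        d = dict(d or {})
        param_over = dict(d.pop("params", {}) or {})
        drive_over = dict(d.pop("drive", {}) or {})
        pfields = {f.name for f in dataclasses.fields(ModelParameters)}
        dfields = {f.name for f in dataclasses.fields(DriveSpec)}
        cfields = {f.name for f in dataclasses.fields(cls)}
        for k in list(d):
            if k in pfields:
                param_over[k] = d.pop(k)
            elif k in dfields:
                drive_over[k] = d.pop(k)
        unknown = set(d) - cfields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        extra = set(param_over) - pfields
        if extra:
            raise ValueError(f"unknown parameter keys: {sorted(extra)}")
        params = ModelParameters().replace(**param_over)
        drive = DriveSpec.from_dict(drive_over)
        return cls(params=params, drive=drive, **d)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a config file; unknown or out-of-range keys
    raise ValueError naming the key.  The effective full parameter set is
    echoed to the package logger."""
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cfg = RunConfig.from_dict(d or {})
    log.info("effective configuration: %s", cfg.to_dict())
    return cfg
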