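"""Run configuration for the command-line workflows (YAML)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .parameters import ModelParameters


@dataclass
class RunConfig:
    """Everything one CLI run needs; round-trips losslessly through YAML."""

    structure: str = ""
    chain: str = "A"
    ss_annotation: Optional[str] = None
    parameters: dict = field(default_factory=dict)   # ModelParameters overrides
    temperatures: list = field(default_factory=lambda: [310.0])
    calibration: dict = field(default_factory=lambda: {"target_tm": 333.0,
                                                       "tol": 0.5})
    elements: dict = field(default_factory=dict)     # name -> [start, end]
    split_block: Optional[int] = None
    threshold_rt: float = 1.0
    contact_cutoff: float = 5.0
    charge_mode: str = "fixed"
    include_termini: bool = True
    pH: float = 7.0
    output_dir: str = "bwsme_out"
    seed: int = 1

    def model_parameters(self) -> ModelParameters:
        known = {f.name for f in dataclasses.fields(ModelParameters)}
        bad = set(self.parameters) - known
        if bad:
            raise ConfigError(f"unknown model parameter(s): {sorted(bad)}")
        return ModelParameters(**self.parameters)

    def element_ranges(self) -> dict:
        out = {}
        for name, (start, end) in self.elements.items():
            out[name] = list(range(int(start), int(end) + 1))
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
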