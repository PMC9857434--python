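"""One-file run configuration aggregating every tunable parameter.

A :class:`RunConfig` parses from YAML or JSON, rejects unknown keys (typos
should never silently fall back to defaults) and echoes itself into every
report so results are reproducible from the report alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .annealing import PartialAnnealingModel
from .design import DesignConfig
from .simulate import (
    Stage,
    ThermalProgram,
    default_primary_program,
    default_secondary_program,
)
from .thermo import ThermoConfig

__all__ = ["RunConfig", "ConfigError", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Raised for unknown keys or malformed configuration blocks."""


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(cls, block: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, names, where)
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


def _program_from(block: dict, where: str, default: ThermalProgram) -> ThermalProgram:
    _check_keys(block, {"stages", "extension_ceiling"}, where)
    stages = []
    for st in block.get("stages", ()):
        _check_keys(st, {"stringency", "cycles", "anneal_c"}, f"{where}.stages")
        stages.append(Stage(st["stringency"], int(st["cycles"]), float(st.get("anneal_c", 0.0))))
    return ThermalProgram(
        tuple(stages) or default.stages,
        int(block.get("extension_ceiling", default.extension_ceiling)),
    )


@dataclass(frozen=True)
class RunConfig:
    thermo: ThermoConfig = field(default_factory=ThermoConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    annealing: PartialAnnealingModel = field(default_factory=PartialAnnealingModel)
    primary_program: ThermalProgram = field(default_factory=default_primary_program)
    secondary_program: ThermalProgram = field(default_factory=default_secondary_program)
    suppression_threshold: int = 200
    seed: int = 0
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        allowed = {
            "thermo", "design", "annealing", "programs",
            "suppression_threshold", "seed", "verbosity", "schema_version",
        }
        _check_keys(data, allowed, "config")
        programs = data.get("programs", {})
        _check_keys(programs, {"primary", "secondary"}, "programs")
        design_block = dict(data.get("design", {}))
        for key in ("overlap_tm_window", "primer_tm_window", "primer_length_window"):
            if key in design_block:
                design_block[key] = tuple(design_block[key])
        return cls(
            thermo=_build(ThermoConfig, dict(data.get("thermo", {})), "thermo"),
            design=_build(DesignConfig, design_block, "design"),
            annealing=_build(PartialAnnealingModel, dict(data.get("annealing", {})), "annealing"),
            primary_program=_program_from(
                dict(programs.get("primary", {})), "programs.primary", default_primary_program()
            ),
            secondary_program=_program_from(
                dict(programs.get("secondary", {})), "programs.secondary",
                default_secondary_program(),
            ),
            suppression_threshold=int(data.get("suppression_threshold", 200)),
            seed=int(data.get("seed", 0)),
            verbosity=str(data.get("verbosity", "info")),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def as_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "thermo": self.thermo.as_dict(),
            "design": self.design.as_dict(),
            "annealing": self.annealing.as_dict(),
            "programs": {
                "primary": self.primary_program.as_dict(),
                "secondary": self.secondary_program.as_dict(),
            },
            "suppression_threshold": self.suppression_threshold,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }
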