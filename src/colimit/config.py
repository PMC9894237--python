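"""Run configuration: strict YAML loading and lossless round-tripping.

The config file is a flat, human-readable YAML document with explicit
units in key names where the dataclass fields carry them (the model is
dense with unit landmines).  Unknown keys are rejected outright - a typo
in ``gamma`` must fail, not silently run the default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cell import CellParams
from .chemistry import CarbonateParams, Environment

__all__ = ["RunConfig", "load_config", "dump_config"]


def _build(cls, mapping: dict, section: str):
    if not isinstance(mapping, dict):
        raise ValueError(f"config section {section!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ValueError(
            f"unknown key(s) {unknown} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {section!r}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable without loss."""

    chemistry: CarbonateParams = field(default_factory=CarbonateParams)
    environment: Environment = field(default_factory=lambda: Environment(pCO2=0.0004))
    cell: CellParams = field(default_factory=CellParams)
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def to_dict(self) -> dict:
        return {
            "chemistry": dataclasses.asdict(self.chemistry),
            "environment": dataclasses.asdict(self.environment),
            "cell": dataclasses.asdict(self.cell),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ValueError("config root must be a mapping")
        known = {"chemistry", "environment", "cell", "seed", "output_dir", "verbosity"}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown top-level config key(s): {unknown}")
        return cls(
            chemistry=_build(CarbonateParams, data.get("chemistry", {}), "chemistry"),
            environment=_build(
                Environment, data.get("environment", {"pCO2": 0.0004}), "environment"
            ),
            cell=_build(CellParams, data.get("cell", {}), "cell"),
            seed=int(data.get("seed", 0)),
            output_dir=str(data.get("output_dir", ".")),
            verbosity=int(data.get("verbosity", 1)),
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (fail-fast on bad keys)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize a RunConfig back to YAML (round-trips losslessly)."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
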