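"""Configuration files, run manifests and result serialization.

Configuration is a YAML (or JSON) mapping with up to five blocks --
``parameters``, ``protocol``, ``grid``, ``timing``, ``criteria``,
``integration`` -- each validated against the corresponding model type.
Missing keys fall back to the built-in defaults (the published parameter
tables), so an empty file, or no file at all, reproduces the reference
configuration.  Unknown keys are rejected with a message naming the field.

Every output directory written by the CLI carries a ``manifest.json`` with
a stable hash of the fully-resolved configuration, the package version and
the integrator settings: two runs with equal manifests produce
byte-identical data files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Dict, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .analysis import TherapeuticCriteria
from .params import ModelParameters
from .protocols import StimulusProtocol, SweepGrid, TimingExperiment

__all__ = ["IntegrationSettings", "RunConfig", "RunManifest", "load_config", "dump_config"]


class IntegrationSettings(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    dt: float = Field(0.02, gt=0, description="Time step (ms)")
    method: str = Field("euler", pattern="^(euler|rk4)$")


class RunConfig(BaseModel):
    """Fully-resolved configuration for any of the experiments."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    parameters: ModelParameters = ModelParameters()
    protocol: Optional[StimulusProtocol] = None
    grid: SweepGrid = SweepGrid()
    timing: TimingExperiment = TimingExperiment()
    criteria: TherapeuticCriteria = TherapeuticCriteria()
    integration: IntegrationSettings = IntegrationSettings()

    def config_hash(self) -> str:
        """Stable hash of the resolved configuration (platform independent)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load and validate a configuration file (YAML or JSON).

    ``None`` or a missing ``parameters`` block yields the default model of
    the published parameter tables.  Validation errors name the offending
    field and constraint.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig) -> str:
    """Serialize a configuration back to normalized YAML.

    Round trip: ``load_config`` of the dumped text validates to an equal
    configuration.
    """
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    config_hash: str
    version: str
    integration: Dict[str, Any]
    outputs: Dict[str, str]
    command: str

    @classmethod
    def create(cls, config: RunConfig, command: str, outputs: Dict[str, str]) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=config.config_hash(),
            version=__version__,
            integration=config.integration.model_dump(),
            outputs=outputs,
            command=command,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")
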