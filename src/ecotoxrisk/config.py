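"""Pipeline configuration: validated, hashable, serialised into outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """Explicit run parameters shared by the CLI stages.

    Every output file records ``config_hash`` and ``seed`` so a run can be
    reproduced exactly, stochastic stages included.
    """

    seed: int = Field(..., ge=0, lt=2**31)
    alpha: float = Field(0.05, gt=0, lt=1)
    af: int = Field(1000, ge=1)
    unit_mode: str = "paper_numeric"
    bootstrap_n: int = Field(1000, ge=0)
    noise_cv: float = Field(0.10, ge=0)
    interaction: str = "additive"
    interaction_strength: float = Field(0.0, ge=0)
    particle_ec50: float = Field(1.0, gt=0)     # % v/v
    particle_hill: float = Field(2.0, gt=0)
    ion_ec50: float = Field(3.0, gt=0)          # % v/v
    ion_hill: float = Field(2.0, gt=0)
    control_mean: float = Field(1.0, gt=0)

    @field_validator("unit_mode")
    @classmethod
    def _check_unit_mode(cls, v: str) -> str:
        if v not in ("si_strict", "paper_numeric"):
            raise ValueError("unit_mode must be si_strict or paper_numeric")
        return v

    @field_validator("interaction")
    @classmethod
    def _check_interaction(cls, v: str) -> str:
        if v not in ("additive", "synergistic", "antagonistic"):
            raise ValueError(
                "interaction must be additive, synergistic or antagonistic"
            )
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def manifest(self, command: str, inputs: list[str], outputs: list[str]) -> dict:
        from . import __version__

        return {
            "command": command,
            "config": self.model_dump(),
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "inputs": inputs,
            "outputs": outputs,
            "version": __version__,
        }
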