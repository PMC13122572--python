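"""Run configuration: schema-validated YAML/JSON settings for the CLI."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import ConfigurationError


class ConstantsOverride(BaseModel):
    model_config = ConfigDict(extra="forbid")
    R: float = 8.314
    F: float = 96485.0


class RunConfig(BaseModel):
    """Top-level settings; unknown keys are rejected at load time."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    constants: ConstantsOverride = Field(default_factory=ConstantsOverride)
    #: Assumed plasma composition, mmol/L (Na is the species value; Cl and K
    #: are generic teleost defaults).
    plasma_mmol: dict[str, float] = Field(
        default_factory=lambda: {"Na": 158.0, "Cl": 130.0, "K": 3.0}
    )
    #: Relative permeabilities with P_Cl = 1 as reference.
    permeability: dict[str, float] = Field(default_factory=lambda: {"Na": 1.95, "Cl": 1.0})
    temperature_c: float = 27.0
    out_dir: str = "."
    verbosity: str = "info"


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or JSON config file (defaults if *path* is None)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalised configuration, for run logs."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]
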