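"""Run configuration: strict parsing, defaults, provenance and round-trip.

Configurations are YAML mappings.  Parsing is strict — unknown keys are
rejected so a typo cannot silently change the physics — and a seed is
mandatory for any stochastic run.  ``provenance`` records, for every field,
whether the value came from the user or from a default.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


class RunConfig(BaseModel):
    """Validated configuration of one simulation run."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    experiment: Literal["elf", "imfp", "track", "beam", "cluster", "microbeam"]
    seed: int
    species: str = "electron"
    energy_ev: float = 100.0
    histories: int = 100
    cutoff_ev: float = 8.23
    box_nm: float | None = None
    depth_mm: float | None = None
    buffer_um: float = 50.0
    voxel_size_nm: float = 2.0
    slab_thickness_nm: float = 2.0
    transverse_extent_nm: float = 1000.0
    out_dir: str = "."
    log_level: Literal["debug", "info", "warning", "error"] = "info"

    def provenance(self) -> dict[str, str]:
        """'user' or 'default' for every field."""
        return {
            name: ("user" if name in self.model_fields_set else "default")
            for name in type(self).model_fields
        }


def parse_config(text: str) -> RunConfig:
    """Parse a YAML run configuration with strict validation.

    Raises :class:`ConfigError` listing the offending keys/locations for
    unknown keys, type mismatches, or a missing seed/experiment.
    """
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping of key: value pairs")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        required = sorted(
            name
            for name, f in RunConfig.model_fields.items()
            if f.is_required() and name not in data
        )
        msg = "invalid configuration: " + "; ".join(lines)
        if required:
            msg += f" (required keys: {', '.join(required)})"
        raise ConfigError(msg) from exc


def serialize_config(config: RunConfig) -> str:
    """YAML round-trip; ``parse_config(serialize_config(c))`` equals ``c``."""
    data = config.model_dump()
    data = {k: v for k, v in data.items() if v is not None}
    return yaml.safe_dump(data, sort_keys=True)
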