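"""Cohort configuration: fractionation, setup-error model, phantom geometry."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration value or unknown field."""


@dataclass
class CohortConfig:
    """Everything needed to generate a synthetic cohort reproducibly.

    Attributes
    ----------
    n_patients, n_fractions, fractions_per_week
        Cohort size and fractionation; defaults 20 patients, 25 fractions of
        2 Gy delivered 5 per week.
    prescription
        Prescribed target dose for the whole course, Gy.
    sigma_systematic, sigma_random
        Per-axis standard deviations (mm) of the systematic (drawn once per
        patient) and random (per fraction) components of the pre-correction
        setup error.
    sigma_residual
        Per-axis SD (mm) of the residual error after image-guided couch
        correction.
    grid_shape
        Voxel counts per axis, ``(nz, ny, nx)``.
    voxel_spacing
        Isotropic voxel size, mm.
    penumbra_width
        80-20% falloff distance (mm) of the planned-dose sigmoid penumbra.
    seed
        Fixes every downstream random draw bit-for-bit.
    """

    n_patients: int = 20
    n_fractions: int = 25
    fractions_per_week: int = 5
    prescription: float = 50.0
    sigma_systematic: float = 3.0
    sigma_random: float = 3.0
    sigma_residual: float = 1.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: float = 4.0
    penumbra_width: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.grid_shape, (list, tuple)):
            self.grid_shape = tuple(int(n) for n in self.grid_shape)
        else:
            raise ConfigError("grid_shape must be a 3-sequence of voxel counts")
        if len(self.grid_shape) != 3:
            raise ConfigError("grid_shape must have exactly three entries")
        for name in ("n_patients", "n_fractions", "fractions_per_week"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if any(n < 1 for n in self.grid_shape):
            raise ConfigError("grid_shape entries must be >= 1")
        for name in ("sigma_systematic", "sigma_random", "sigma_residual",
                     "penumbra_width"):
            if float(getattr(self, name)) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.prescription <= 0:
            raise ConfigError("prescription must be > 0")
        if self.voxel_spacing <= 0:
            raise ConfigError("voxel_spacing must be > 0")
        self.seed = int(self.seed)
        if not (0 <= self.seed < 2**31):
            raise ConfigError("seed must lie in [0, 2^31)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown cohort config field(s): {sorted(unknown)}; "
                f"valid fields: {sorted(known)}"
            )
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        data = load_config_file(path)
        block = data.get("cohort", data)
        if not isinstance(block, dict):
            raise ConfigError("cohort config block must be a mapping")
        return cls.from_dict(block)

    def digest(self) -> str:
        """SHA-256 of the canonical JSON encoding (provenance hash)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML/JSON: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return data
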