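"""Dose grids and structure masks on a shared regular voxel lattice.

Conventions (fixed to avoid geometry drift):

* array index order is ``(z, y, x)``;
* physical axes: x = lateral, y = anterior-posterior, z = superior-inferior;
* voxel spacing is isotropic, in millimetres; dose in Gy;
* shift vectors are given in physical ``(x, y, z)`` order, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRUCTURE_NAMES = ("PTVsc", "PTVcw", "heart", "lung_ipsi", "breast_contra")


class GeometryError(ValueError):
    """Grids or masks do not share the same lattice."""


@dataclass
class DoseGrid:
    """3-D scalar dose field on a regular grid.

    Parameters
    ----------
    values
        Non-negative dose per voxel in Gy, array indexed ``(z, y, x)``.
    spacing
        Isotropic voxel spacing in mm.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` corner, ``(x, y, z)`` mm.
    """

    values: np.ndarray
    spacing: float = 4.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GeometryError(f"dose grid must be 3-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose grid contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("dose grid contains negative values")
        if self.spacing <= 0:
            raise GeometryError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_geometry(self, other: "DoseGrid | StructureMask") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "DoseGrid | StructureMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}@{self.spacing}mm vs "
                f"{other.shape}@{other.spacing}mm"
            )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        return DoseGrid(values, spacing=self.spacing, origin=self.origin)


@dataclass
class StructureMask:
    """Boolean occupancy field for one anatomical structure.

    Masks live in the planning frame: delivered doses move under setup error,
    the masks do not.
    """

    name: str
    values: np.ndarray
    spacing: float = 4.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {self.values.shape}")
        if not self.values.any():
            raise ValueError(f"structure mask '{self.name}' is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())
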