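"""Dose accumulation, cumulative DVHs, and DVH-derived metrics."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .grid import DoseGrid, StructureMask, GeometryError

DEFAULT_BIN_WIDTH = 0.05  # Gy; fine enough that binning error << ~1% of 50 Gy


def accumulate(doses: Sequence[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of dose grids sharing one geometry."""
    doses = list(doses)
    if not doses:
        raise ValueError("cannot accumulate an empty list of dose grids")
    first = doses[0]
    total = np.zeros_like(first.values)
    for d in doses:
        first.require_same_geometry(d)
        total += d.values
    return first.with_values(total)


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``cum_volume[i]`` is the fraction of the structure receiving at least
    ``edges[i]`` Gy.  The curve starts at 1.0 at 0 Gy, is monotone
    nonincreasing, and ends at 0 beyond the maximum dose.  Edges are uniform
    (width ``bin_width``) for freshly computed DVHs and may be nonuniform
    after a dose-axis transform (e.g. conversion to EQD2).
    """

    structure: str
    edges: np.ndarray          # Gy, increasing, edges[0] == 0
    cum_volume: np.ndarray     # same length as edges
    n_voxels: int
    bin_width: float | None = DEFAULT_BIN_WIDTH

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.cum_volume = np.asarray(self.cum_volume, dtype=float)
        if self.edges.shape != self.cum_volume.shape or self.edges.ndim != 1:
            raise ValueError("edges and cum_volume must be 1-D arrays of equal length")
        if self.edges.size < 2:
            raise ValueError("a DVH needs at least two edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("DVH edges must be strictly increasing")
        if np.any(np.diff(self.cum_volume) > 1e-12):
            raise ValueError("cumulative volume must be monotone nonincreasing")

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Bin midpoints and fractional volumes (sum to 1) of the differential DVH."""
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        vols = -np.diff(self.cum_volume)
        return mids, vols

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dose_gy", "cum_volume_fraction"])
            for d, v in zip(self.edges, self.cum_volume):
                writer.writerow([f"{d:.10g}", f"{v:.10g}"])

    @classmethod
    def from_csv(cls, path: str | Path, structure: str = "", n_voxels: int = 0) -> "DVH":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(structure or Path(path).stem, data[:, 0], data[:, 1],
                   n_voxels, bin_width=None)


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVH:
    """Cumulative DVH of ``dose`` over the voxels of ``mask``."""
    dose.require_same_geometry(mask)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not mask.values.any():
        raise ValueError(f"structure mask '{mask.name}' is empty")
    voxels = dose.values[mask.values]
    top = float(voxels.max())
    n_bins = max(1, int(np.ceil(top / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(voxels, bins=edges)
    cum = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]]) / voxels.size
    return DVH(mask.name, edges, cum, voxels.size, bin_width=bin_width)


def dose_at_volume(dvh: DVH, volume_fraction: float) -> float:
    """Dose D such that a fraction ``volume_fraction`` of the structure
    receives at least D (e.g. 0.95 for D95).

    Linear interpolation on the cumulative curve; when a flat segment of the
    curve equals the query volume, the lower dose is returned.
    """
    if not (0 < volume_fraction <= 1):
        raise ValueError("volume fraction must lie in (0, 1]")
    cum, edges = dvh.cum_volume, dvh.edges
    below = np.nonzero(cum < volume_fraction)[0]
    if below.size == 0:  # whole curve >= query: D is beyond the last edge
        return float(edges[-1])
    j = below[0]
    if j == 0:
        return float(edges[0])
    c0, c1 = cum[j - 1], cum[j]
    d0, d1 = edges[j - 1], edges[j]
    return float(d0 + (c0 - volume_fraction) / (c0 - c1) * (d1 - d0))


def dvh_metric(dvh: DVH, metric: str) -> float:
    """Evaluate a named DVH metric: ``D95``, ``Dmean`` or ``Dmax`` (Gy)."""
    metric_l = metric.lower()
    if metric_l == "d95":
        return dose_at_volume(dvh, 0.95)
    if metric_l == "dmean":
        mids, vols = dvh.differential()
        return float(np.sum(mids * vols))
    if metric_l == "dmax":
        _, vols = dvh.differential()
        nz = np.nonzero(vols > 0)[0]
        return float(dvh.edges[nz[-1] + 1]) if nz.size else float(dvh.edges[1])
    raise ValueError(f"unknown DVH metric '{metric}'; expected D95, Dmean or Dmax")
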