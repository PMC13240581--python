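"""Synthetic cohort generator.

Emulates the per-fraction dosimetric consequences of patient setup error in a
fractionated chest-wall course. For every fraction a patient carries a
pre-correction setup error (systematic per-patient component plus random
per-fraction component) and, after image-guided couch correction, a small
residual error. The dose actually delivered in each positional state is
modelled by rigidly translating the planned dose distribution and resampling
it on the planning grid (invariant-dose approximation) — this stands in for
full deformable-registration-based per-fraction recalculation and is the
module's central simplification.

Phantom geometry (left chest wall, supraclavicular target, heart, ipsilateral
lung, contralateral breast) is defined in fractional grid coordinates so the
same structure set scales with grid size; error magnitudes and the dose
penumbra remain in absolute millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import scipy.ndimage as ndi
from scipy.special import expit

from .config import CohortConfig, ConfigError
from .grid import DoseGrid, StructureMask, GeometryError, STRUCTURE_NAMES

MANIFEST_NAME = "manifest.json"
FORMAT_VERSION = 1

# ---------------------------------------------------------------------------
# setup errors


class GenerationError(RuntimeError):
    """Phantom or cohort generation failed (e.g. structure truncated)."""


@dataclass
class SetupErrorSeries:
    """Per-fraction rigid translational setup errors for one patient.

    ``pre_shift[f]`` is the pre-correction error of fraction ``f`` (systematic
    patient mean plus random component), ``post_shift[f]`` the residual error
    after image-guided correction.  Shape ``(n_fractions, 3)``, physical
    ``(x, y, z)`` order, mm.
    """

    patient_id: int
    pre_shift: np.ndarray
    post_shift: np.ndarray

    def __post_init__(self) -> None:
        self.pre_shift = np.asarray(self.pre_shift, dtype=float)
        self.post_shift = np.asarray(self.post_shift, dtype=float)
        if self.pre_shift.shape != self.post_shift.shape or self.pre_shift.shape[1:] != (3,):
            raise ValueError("shift arrays must both have shape (n_fractions, 3)")

    @property
    def n_fractions(self) -> int:
        return self.pre_shift.shape[0]


def sample_setup_errors(config: CohortConfig, patient_id: int) -> SetupErrorSeries:
    """Draw the setup-error series for one patient.

    The pre-correction error of fraction *f* is ``mu_p + eps_f`` with the
    systematic component ``mu_p ~ N(0, sigma_systematic^2)`` drawn once per
    patient per axis and the random component ``eps_f ~ N(0, sigma_random^2)``
    drawn per fraction.  The post-correction residual is
    ``N(0, sigma_residual^2)`` per fraction per axis.  Fully determined by
    ``(config.seed, patient_id)``.
    """
    rng = np.random.default_rng((config.seed, int(patient_id), 0x5E))
    mu = rng.normal(0.0, config.sigma_systematic, size=3)
    eps = rng.normal(0.0, config.sigma_random, size=(config.n_fractions, 3))
    residual = rng.normal(0.0, config.sigma_residual, size=(config.n_fractions, 3))
    return SetupErrorSeries(int(patient_id), mu[None, :] + eps, residual)


# ---------------------------------------------------------------------------
# phantom

# Structure geometry in fractional grid coordinates (u=x, v=y, w=z in [0,1]).
# +x = patient left, +y = posterior, +z = superior.  The chest-wall target is
# a curved anterior-left slab; the supraclavicular target a small superior
# box; heart medial and deep to the slab; ipsilateral lung beneath it;
# contralateral breast on the right side.
_SLAB_U = (0.50, 0.80)
_SLAB_W = (0.25, 0.65)
_SLAB_V0, _SLAB_CURV, _SLAB_T = 0.26, 0.8, 0.10
_SC_BOX = ((0.54, 0.76), (0.26, 0.44), (0.70, 0.86))  # (u, v, w) ranges
_HEART = ((0.46, 0.52, 0.34), (0.12, 0.12, 0.14))     # center, semi-axes
_LUNG = ((0.66, 0.50, 0.45), (0.15, 0.20, 0.26))
_BREAST = ((0.30, 0.34, 0.45), (0.12, 0.10, 0.14))


def _frac_coords(shape: tuple[int, int, int]):
    nz, ny, nx = shape
    w = ((np.arange(nz) + 0.5) / nz)[:, None, None]
    v = ((np.arange(ny) + 0.5) / ny)[None, :, None]
    u = ((np.arange(nx) + 0.5) / nx)[None, None, :]
    return u, v, w


def _ellipsoid(u, v, w, center, semi) -> np.ndarray:
    cu, cv, cw = center
    au, av, aw = semi
    return ((u - cu) / au) ** 2 + ((v - cv) / av) ** 2 + ((w - cw) / aw) ** 2 <= 1.0


def _check_untruncated(name: str, mask: np.ndarray) -> None:
    faces = (mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[:, :, 0], mask[:, :, -1])
    if any(f.any() for f in faces):
        raise GenerationError(f"structure '{name}' is truncated by the grid boundary")


def build_phantom(config: CohortConfig) -> tuple[DoseGrid, dict[str, StructureMask]]:
    """Build the planning-frame phantom: structure masks and planned dose.

    The planned dose equals the prescription throughout the PTV union and
    falls to zero background through a sigmoid penumbra whose 80-20% falloff
    distance is ``penumbra_width``; the 50% level sits 1.5x that width outside
    the PTV surface so the prescription isodose covers the PTV with margin
    (clinically, conformity tuned so the plan-quality gate D95 >= 95% of
    prescription holds).  Organs at risk receive incidental dose by proximity.
    """
    u, v, w = _frac_coords(config.grid_shape)

    slab_floor = _SLAB_V0 + _SLAB_CURV * (u - _SLAB_U[0]) ** 2
    ptv_cw = (
        (u >= _SLAB_U[0]) & (u <= _SLAB_U[1])
        & (v >= slab_floor) & (v <= slab_floor + _SLAB_T)
        & (w >= _SLAB_W[0]) & (w <= _SLAB_W[1])
    )
    (su, sv, sw) = _SC_BOX
    ptv_sc = (
        (u >= su[0]) & (u <= su[1])
        & (v >= sv[0]) & (v <= sv[1])
        & (w >= sw[0]) & (w <= sw[1])
    )
    ptv_sc &= ~ptv_cw  # targets must be disjoint (slab curvature never reaches, but enforce)
    ptv = ptv_cw | ptv_sc

    heart = _ellipsoid(u, v, w, *_HEART) & ~ptv
    lung = _ellipsoid(u, v, w, *_LUNG) & ~ptv
    breast = _ellipsoid(u, v, w, *_BREAST) & ~ptv

    arrays = {
        "PTVsc": ptv_sc,
        "PTVcw": ptv_cw,
        "heart": heart,
        "lung_ipsi": lung,
        "breast_contra": breast,
    }
    masks: dict[str, StructureMask] = {}
    for name in STRUCTURE_NAMES:
        arr = arrays[name]
        if not arr.any():
            raise GenerationError(f"structure '{name}' is empty on grid {config.grid_shape}")
        _check_untruncated(name, arr)
        masks[name] = StructureMask(name, arr, spacing=config.voxel_spacing)

    spacing = config.voxel_spacing
    d_out = ndi.distance_transform_edt(~ptv, sampling=spacing)
    d_in = ndi.distance_transform_edt(ptv, sampling=spacing)
    signed = d_out - d_in  # negative inside the PTV
    width = config.penumbra_width
    if width > 0:
        # logistic scale such that the 80-20% falloff spans `width` mm
        k = width / (2.0 * np.log(4.0))
        dose = config.prescription * expit(-(signed - 1.5 * width) / k)
    else:
        dose = np.where(signed < 0, config.prescription, 0.0)
    planned = DoseGrid(dose, spacing=spacing)
    return planned, masks


# ---------------------------------------------------------------------------
# fraction delivery


@dataclass
class FractionDose:
    """Delivered dose of one fraction in both positional states."""

    fraction_index: int  # 1-based
    dose_pre: DoseGrid
    dose_post: DoseGrid

    def __post_init__(self) -> None:
        self.dose_pre.require_same_geometry(self.dose_post)


def deliver_fraction(planned: DoseGrid, shift_mm, n_fractions: int) -> DoseGrid:
    """Dose delivered in one fraction with the patient displaced by ``shift_mm``.

    With the patient moved by ``+s`` relative to the beams, the dose pattern
    moves by ``-s`` in the planning frame: the returned grid samples
    ``planned`` at coordinates translated by ``+s`` (trilinear interpolation,
    out-of-grid treated as zero background) and scales by ``1/n_fractions``.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    shift_mm = np.asarray(shift_mm, dtype=float)
    if shift_mm.shape != (3,):
        raise ValueError("shift must be a 3-vector (x, y, z) in mm")
    extent = np.array(planned.shape[::-1]) * planned.spacing
    if np.any(np.abs(shift_mm) >= extent):
        raise ValueError(f"shift {shift_mm} exceeds grid extent {extent} mm")
    # array axes are (z, y, x); out[i] = planned[i + s] -> ndi.shift by -s
    shift_vox = shift_mm[::-1] / planned.spacing
    values = ndi.shift(
        planned.values, shift=-shift_vox, order=1,
        mode="constant", cval=0.0, prefilter=False,
    )
    np.maximum(values, 0.0, out=values)
    return planned.with_values(values / n_fractions)


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class Cohort:
    """A cohort: shared phantom plus per-patient setup errors.

    Per-fraction dose grids are produced on demand by :meth:`fractions` —
    either synthesized from the planned dose and stored errors, or read from
    an on-disk cohort directory — so full cohorts need not be held in memory.
    """

    config: CohortConfig
    planned: DoseGrid
    masks: dict[str, StructureMask]
    errors: dict[int, SetupErrorSeries]
    _loader: Callable[[int], list[FractionDose]] | None = None

    @property
    def patient_ids(self) -> list[int]:
        return sorted(self.errors)

    def fractions(self, patient_id: int) -> list[FractionDose]:
        if patient_id not in self.errors:
            raise KeyError(f"patient {patient_id} not in cohort")
        if self._loader is not None:
            return self._loader(patient_id)
        series = self.errors[patient_id]
        out = []
        for f in range(self.config.n_fractions):
            out.append(
                FractionDose(
                    f + 1,
                    deliver_fraction(self.planned, series.pre_shift[f], self.config.n_fractions),
                    deliver_fraction(self.planned, series.post_shift[f], self.config.n_fractions),
                )
            )
        return out


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Build the in-memory cohort for ``config`` (fraction doses lazy)."""
    planned, masks = build_phantom(config)
    errors = {
        pid: sample_setup_errors(config, pid)
        for pid in range(1, config.n_patients + 1)
    }
    return Cohort(config, planned, masks, errors)


# ---------------------------------------------------------------------------
# on-disk container


def _write_f32(path: Path, values: np.ndarray) -> None:
    np.asarray(values, dtype="<f4").tofile(path)


def _read_f32(path: Path, shape) -> np.ndarray:
    return np.fromfile(path, dtype="<f4").reshape(shape).astype(np.float64)


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write it to ``out_dir``.

    Layout: one directory per patient with a JSON header, raw little-endian
    float32 arrays per dose grid (``planned.f32``, ``fxNNN_pre.f32``,
    ``fxNNN_post.f32``) and uint8 masks; a top-level ``manifest.json`` listing
    patients, fractions and seeds.  The manifest is written last, so a partial
    write leaves no valid manifest.  Byte-for-byte reproducible from
    ``config`` (including its seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)

    patients = []
    for pid in cohort.patient_ids:
        pdir = out_dir / f"patient_{pid:03d}"
        pdir.mkdir(exist_ok=True)
        series = cohort.errors[pid]
        header = {
            "patient_id": pid,
            "grid_shape": list(config.grid_shape),
            "spacing_mm": config.voxel_spacing,
            "origin_mm": [0.0, 0.0, 0.0],
            "axis_order": "zyx",
            "shift_order": "xyz",
            "structures": list(STRUCTURE_NAMES),
            "n_fractions": config.n_fractions,
            "seed": config.seed,
            "pre_shift_mm": series.pre_shift.tolist(),
            "post_shift_mm": series.post_shift.tolist(),
        }
        (pdir / "header.json").write_text(json.dumps(header, sort_keys=True, indent=1))
        _write_f32(pdir / "planned.f32", cohort.planned.values)
        for name, mask in cohort.masks.items():
            mask.values.astype(np.uint8).tofile(pdir / f"mask_{name}.u8")
        for fx in cohort.fractions(pid):
            _write_f32(pdir / f"fx{fx.fraction_index:03d}_pre.f32", fx.dose_pre.values)
            _write_f32(pdir / f"fx{fx.fraction_index:03d}_post.f32", fx.dose_post.values)
        patients.append({"patient_id": pid, "dir": pdir.name, "n_fractions": config.n_fractions})

    manifest = {
        "format_version": FORMAT_VERSION,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "structures": list(STRUCTURE_NAMES),
        "patients": patients,
    }
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out_dir


def load_cohort(cohort_dir: str | Path) -> Cohort:
    """Load an on-disk cohort written by :func:`generate_cohort`.

    Fraction dose grids are read lazily per patient.
    """
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / MANIFEST_NAME
    if not manifest_path.is_file():
        raise FileNotFoundError(f"no cohort manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    config = CohortConfig.from_dict(manifest["config"])
    shape = config.grid_shape
    spacing = config.voxel_spacing

    first = cohort_dir / manifest["patients"][0]["dir"]
    planned = DoseGrid(_read_f32(first / "planned.f32", shape), spacing=spacing)
    masks = {
        name: StructureMask(
            name,
            np.fromfile(first / f"mask_{name}.u8", dtype=np.uint8).reshape(shape).astype(bool),
            spacing=spacing,
        )
        for name in manifest["structures"]
    }
    errors: dict[int, SetupErrorSeries] = {}
    dirs: dict[int, Path] = {}
    for entry in manifest["patients"]:
        pid = int(entry["patient_id"])
        pdir = cohort_dir / entry["dir"]
        header = json.loads((pdir / "header.json").read_text())
        errors[pid] = SetupErrorSeries(
            pid, np.array(header["pre_shift_mm"]), np.array(header["post_shift_mm"])
        )
        dirs[pid] = pdir

    def loader(pid: int) -> list[FractionDose]:
        pdir = dirs[pid]
        out = []
        for f in range(1, config.n_fractions + 1):
            pre = pdir / f"fx{f:03d}_pre.f32"
            post = pdir / f"fx{f:03d}_post.f32"
            if not pre.is_file() or not post.is_file():
                raise FileNotFoundError(
                    f"missing fraction data for patient {pid}, fraction {f}"
                )
            out.append(
                FractionDose(
                    f,
                    DoseGrid(_read_f32(pre, shape), spacing=spacing),
                    DoseGrid(_read_f32(post, shape), spacing=spacing),
                )
            )
        return out

    return Cohort(config, planned, masks, errors, _loader=loader)
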