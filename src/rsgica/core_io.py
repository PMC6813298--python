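"""In-memory study model and NIfTI / motion-text / manifest I/O.

The pipeline operates on volumes already resampled to one common grid
(the phantom is generated there directly); grids are therefore required
to match exactly and nothing is ever silently resampled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .config import StudyConfig
from .errors import (
    GridMismatchError,
    InvalidVolumeError,
    MissingInputError,
    MotionLengthMismatchError,
)

MASK_ROLES = ("brain", "grey", "white", "csf", "susceptibility_boundary", "vessel")
#: roles that must be nonempty in a valid study
REQUIRED_NONEMPTY = ("brain", "grey", "white", "csf")


@dataclass
class Volume4D:
    """A 4D BOLD grid (x, y, z, t) with voxel geometry and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[3] < 1:
            raise InvalidVolumeError(
                f"expected 4D data with t >= 1, got shape {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise InvalidVolumeError("volume contains NaN values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise InvalidVolumeError("affine must be 4x4")
        if self.tr_s <= 0:
            raise InvalidVolumeError(f"tr_s must be positive, got {self.tr_s}")
        if np.any(self.voxel_size_mm <= 0):
            raise InvalidVolumeError("voxel sizes must be strictly positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MaskVolume:
    """A binary 3D mask with a named role (brain, grey, white, csf, ...)."""

    data: np.ndarray
    affine: np.ndarray
    role: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise InvalidVolumeError(
                f"mask '{self.role}' must be binary, found values {vals[:5]}"
            )
        self.data = arr.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.role in REQUIRED_NONEMPTY and not self.data.any():
            raise InvalidVolumeError(f"mask '{self.role}' is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: tx, ty, tz (mm), rx, ry, rz (deg)."""

    params: np.ndarray  # (t, 6)

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise InvalidVolumeError(
                f"motion trace needs 6 columns, got {self.params.shape[1]}"
            )
        if not np.isfinite(self.params).all():
            raise InvalidVolumeError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class SubjectRun:
    """One functional run of one subject."""

    subject_id: str
    run_index: int
    volume: Volume4D
    motion: MotionTrace

    def __post_init__(self) -> None:
        if self.run_index not in (1, 2):
            raise InvalidVolumeError(
                f"run_index must be 1 or 2, got {self.run_index}"
            )
        if self.motion.n_volumes != self.volume.n_volumes:
            raise MotionLengthMismatchError(
                f"{self.subject_id} run {self.run_index}: motion rows "
                f"({self.motion.n_volumes}) != volumes ({self.volume.n_volumes})"
            )

    @property
    def retained_volume_count(self) -> int:
        return self.volume.n_volumes


@dataclass
class Study:
    """A validated collection of subject runs sharing one grid, plus masks."""

    runs: list[SubjectRun]
    masks: dict[str, MaskVolume]
    config: StudyConfig
    truth: object | None = None  # PhantomTruth when simulated

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.runs[0].volume.shape3d

    def runs_for(self, run_index: int) -> list[SubjectRun]:
        return [r for r in self.runs if r.run_index == run_index]

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            if r.subject_id not in seen:
                seen.append(r.subject_id)
        return seen


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def save_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a Volume4D as NIfTI-1 with the TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms((*vol.voxel_size_mm, vol.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    try:
        nib.save(img, str(path))
    except OSError as exc:  # unwritable path
        raise MissingInputError(f"cannot write {path}: {exc}") from exc
    return path


def load_volume(path: str | Path, tr_s: float | None = None) -> Volume4D:
    """Read a 4D NIfTI; TR taken from the header unless overridden."""
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data=data, affine=img.affine, tr_s=tr_s)


def round_trip_volume(vol: Volume4D, path: str | Path) -> Volume4D:
    """Write then re-read a volume; geometry is preserved exactly and voxel
    data to float32 storage precision."""
    save_volume(vol, path)
    return load_volume(path, tr_s=vol.tr_s)


def save_mask(mask: MaskVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


def load_mask(path: str | Path, role: str) -> MaskVolume:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"no such mask file: {path}")
    img = nib.load(str(path))
    return MaskVolume(data=np.asanyarray(img.dataobj), affine=img.affine, role=role)


# ---------------------------------------------------------------------------
# Motion text (rp-style: 6 whitespace-delimited columns)
# ---------------------------------------------------------------------------

def save_motion(trace: MotionTrace, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, trace.params, fmt="%.6f")
    return path


def load_motion(path: str | Path, rotations_in_radians: bool = False) -> MotionTrace:
    """Read a 6-column realignment-parameter file.

    Columns are tx, ty, tz (mm) then rx, ry, rz.  Rotations are taken as
    degrees by default; pass ``rotations_in_radians=True`` for files in the
    radian convention of common realignment packages.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"no such motion file: {path}")
    params = np.atleast_2d(np.loadtxt(path))
    if rotations_in_radians and params.size:
        params = params.copy()
        params[:, 3:] = np.degrees(params[:, 3:])
    return MotionTrace(params=params)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def load_study(manifest_path: str | Path) -> Study:
    """Assemble a validated Study from a YAML manifest.

    The manifest lists per-run image/motion files, mask files, and optional
    config overrides; all paths are resolved relative to the manifest.
    Any grid mismatch or motion/volume length mismatch raises a distinct
    named error; nothing is resampled.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingInputError(f"no such manifest: {manifest_path}")
    root = manifest_path.parent
    spec = yaml.safe_load(manifest_path.read_text())

    config = StudyConfig.from_dict(spec.get("config", {}))

    masks: dict[str, MaskVolume] = {}
    for role, rel in (spec.get("masks") or {}).items():
        if role not in MASK_ROLES:
            raise InvalidVolumeError(f"unknown mask role '{role}'")
        masks[role] = load_mask(root / rel, role)

    runs: list[SubjectRun] = []
    for entry in spec.get("runs", []):
        vol = load_volume(root / entry["bold"], tr_s=config.tr_s)
        motion = load_motion(
            root / entry["motion"],
            rotations_in_radians=config.rotations_in_radians,
        )
        runs.append(
            SubjectRun(
                subject_id=str(entry["subject"]),
                run_index=int(entry["run"]),
                volume=vol,
                motion=motion,
            )
        )
    if not runs:
        raise MissingInputError(f"manifest {manifest_path} lists no runs")

    ref_shape = runs[0].volume.shape3d
    ref_affine = runs[0].volume.affine
    for r in runs:
        _check_grid(r.volume.shape3d, r.volume.affine, ref_shape, ref_affine,
                    f"run {r.subject_id}/{r.run_index}")
    for role, m in masks.items():
        _check_grid(m.data.shape, m.affine, ref_shape, ref_affine, f"mask {role}")

    return Study(runs=runs, masks=masks, config=config)


def _check_grid(shape, affine, ref_shape, ref_affine, what: str) -> None:
    if tuple(shape) != tuple(ref_shape):
        raise GridMismatchError(
            f"{what}: grid {tuple(shape)} != reference {tuple(ref_shape)}"
        )
    if not np.allclose(affine, ref_affine, atol=1e-4):
        raise GridMismatchError(f"{what}: affine differs from reference")
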