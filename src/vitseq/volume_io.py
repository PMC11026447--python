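"""NIfTI volume I/O and the axis conventions shared by the whole pipeline.

Every downstream module assumes the canonical axis order

    x: left -> right, y: posterior -> anterior, z: inferior -> superior

(i.e. RAS+). Volumes read from disk are reoriented to this convention from
their header; the array handed out is therefore always (x, y, z). On the
MNI-registered 113x137x113 grid this makes the axial slice x*y = 113x137,
the coronal slice x*z = 113x113 and the sagittal slice y*z = 137x113.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D", "CorruptVolumeError", "DegenerateVolumeError",
    "read_volume", "write_volume", "normalize", "validate_grid",
    "default_affine", "write_manifest", "read_manifest", "MNI_GRID",
]

#: voxel grid of the MNI-registered inputs the pipeline expects
MNI_GRID: tuple[int, int, int] = (113, 137, 113)


class CorruptVolumeError(ValueError):
    """The file is not a readable NIfTI-1 volume (bad magic, truncated, ...)."""


class DegenerateVolumeError(ValueError):
    """The volume carries no usable intensity contrast (e.g. constant)."""


@dataclass
class Volume3D:
    """One 3D scan: voxel intensities plus grid metadata and optional label.

    ``data`` is indexed (x, y, z) in the canonical orientation above.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label: str | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-axis, got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def default_affine(shape: tuple[int, int, int],
                   voxel_mm: float = 1.5) -> np.ndarray:
    """Isotropic RAS+ affine centring the grid on the world origin."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    return aff


def read_volume(path: str | Path, label: str | None = None,
                subject_id: str | None = None) -> Volume3D:
    """Load a NIfTI-1 file and reorient it to the canonical (LR, PA, IS) axes.

    Intensities are returned untouched; call :func:`normalize` separately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)  # RAS+ == our convention
        data = np.asarray(img.dataobj, dtype=np.float64)
    except (nib.filebasedimages.ImageFileError, OSError, EOFError) as exc:
        raise CorruptVolumeError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise CorruptVolumeError(f"{path}: expected a 3-axis volume, got {data.ndim}")
    return Volume3D(data=data, affine=np.asarray(img.affine),
                    label=label, subject_id=subject_id)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii or .nii.gz), float64 for lossless round trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))
    return path


def normalize(vol: Volume3D) -> Volume3D:
    """Affine min-max rescale of intensities to [0, 1]; idempotent.

    Raises :class:`DegenerateVolumeError` on constant or non-finite input.
    """
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise DegenerateVolumeError("volume contains non-finite intensities")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        raise DegenerateVolumeError("constant volume: max == min, cannot rescale")
    return Volume3D(data=(data - lo) / (hi - lo), affine=vol.affine,
                    label=vol.label, subject_id=vol.subject_id)


def validate_grid(vol: Volume3D, expected_shape: tuple[int, int, int] = MNI_GRID,
                  strict: bool = False, warn: bool = True) -> bool:
    """True iff the volume sits on ``expected_shape`` (order-sensitive).

    The method itself generalizes to other grids, so a mismatch warns rather
    than fails unless ``strict``.
    """
    ok = tuple(vol.shape) == tuple(expected_shape)
    if not ok:
        msg = f"volume grid {vol.shape} != expected {tuple(expected_shape)}"
        if strict:
            raise ValueError(msg)
        if warn:
            warnings.warn(msg, stacklevel=2)
    return ok


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Dataset manifest CSV with columns filename, label, subject_id."""
    path = Path(path)
    pd.DataFrame(rows, columns=["filename", "label", "subject_id"]).to_csv(
        path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
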