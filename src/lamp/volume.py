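"""3-D medical-image volumes and standardisation to the canonical frame.

The pipeline works in a single canonical frame: RAI axis order (first axis
runs Right-to-left, second Anterior-to-posterior, third Inferior-to-superior)
and 1 mm isotropic voxels.  World positions are voxel-centre based with
0-based indices, in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """Raised when a file cannot be read as a 3-D NIfTI volume."""


class OrientationError(ValueError):
    """Raised when axis-orientation codes are missing or invalid."""


#: "from" codes: the anatomical side a data axis starts at.  The canonical
#: frame is "RAI": x Right-to-left, y Anterior-to-posterior, z Inferior-to-superior.
_FROM_TO = {"R": "L", "L": "R", "A": "P", "P": "A", "I": "S", "S": "I"}


@dataclass
class Volume:
    """A 3-D scalar (intensity) or integer (label) grid with geometry.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  Label volumes hold non-negative integers.
    affine : ndarray, shape (4, 4)
        Voxel-index -> world (mm) map, voxel-centre convention.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D volume, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each data axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        """World position (mm) of the centre of voxel (0, 0, 0)."""
        return self.affine[:3, 3].copy()

    @property
    def orientation(self) -> str:
        """Three 'from' codes, e.g. ``"RAI"`` for the canonical frame.

        nibabel's axis codes name the side an axis points *towards*; the
        codes here name the side it starts *from*, matching the RAI
        convention used throughout the pipeline.
        """
        try:
            to_codes = nib.orientations.aff2axcodes(self.affine)
        except Exception as exc:  # pragma: no cover - defensive
            raise OrientationError(f"cannot derive orientation from affine: {exc}") from exc
        return "".join(_FROM_TO[c] for c in to_codes)

    @property
    def is_label(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm positions."""
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def read_volume(path) -> Volume:
    """Read a NIfTI-1/NIfTI-2 file into a :class:`Volume`."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read NIfTI volume at {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!s}: expected a 3-D image, got shape {data.shape}")
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI (suffix decides .nii / .nii.gz)."""
    data = volume.data
    if volume.is_label:
        data = data.astype(np.int16, copy=False)
    else:
        data = data.astype(np.float32, copy=False)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


def reorient_to_rai(volume: Volume) -> Volume:
    """Permute/flip axes so the volume sits in the canonical RAI frame.

    Voxel values are never interpolated and every voxel keeps its world
    position; only the array layout and the affine change.
    """
    if volume.orientation == "RAI":
        return volume
    # RAI "from" codes correspond to nibabel "towards" codes ('L','P','S').
    current = nib.orientations.io_orientation(volume.affine)
    if np.any(np.isnan(current)):
        raise OrientationError("volume affine has ambiguous axis orientations")
    target = nib.orientations.axcodes2ornt(("L", "P", "S"))
    transform = nib.orientations.ornt_transform(current, target)
    data = nib.orientations.apply_orientation(volume.data, transform)
    affine = volume.affine @ nib.orientations.inv_ornt_aff(transform, volume.data.shape)
    return Volume(data=data, affine=affine)


def resample_isotropic(volume: Volume, target_spacing: float = 1.0) -> Volume:
    """Resample to isotropic voxels of ``target_spacing`` mm.

    Intensity volumes are interpolated trilinearly, label volumes by nearest
    neighbour.  Voxel (0,0,0) keeps its world position; the world extent is
    preserved to within one voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    spacing = volume.spacing
    if np.allclose(spacing, target_spacing):
        return volume
    old_shape = np.array(volume.data.shape)
    new_shape = np.maximum(1, np.round(old_shape * spacing / target_spacing)).astype(int)
    # new voxel-centre i maps to old fractional index i * t / s
    scale = target_spacing / spacing
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(new_shape, scale)], indexing="ij")
    coords = np.stack(grids)
    order = 0 if volume.is_label else 1
    data = ndimage.map_coordinates(volume.data, coords, order=order, mode="nearest")
    data = data.reshape(new_shape)
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = volume.affine[:3, :3] * scale[np.newaxis, :]
    return Volume(data=data, affine=new_affine)
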