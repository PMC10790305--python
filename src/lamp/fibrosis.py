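"""LGE fibrosis mapping onto the atrial surface.

Wall intensity is estimated per element by maximum-intensity projection of
the LGE volume along the element normal, thresholded by the image-intensity
ratio (IIR): threshold = mean bloodpool intensity × factor.  The fibrosis
score is the fraction of left-atrial-body surface area at or above
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lamp.mesh import LabelledSurfaceMesh, STRUCTURE_LABELS
from lamp.volume import Volume

#: Factors commonly used for the image-intensity-ratio threshold.
DEFAULT_IIR_FACTORS = (0.97, 1.2, 1.32)


@dataclass
class IntensityMap:
    """Per-element projected intensity; NaN marks elements outside the volume."""

    values: np.ndarray
    depth: float  # projection half-depth, mm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)


@dataclass
class FibrosisSummary:
    iir_factor: float
    threshold: float
    score: float  # fraction of LA-body area at/above threshold, in [0, 1]
    normalised: np.ndarray | None = field(default=None, repr=False)


def project_max_intensity(
    mesh: LabelledSurfaceMesh, lge: Volume, depth: float = 3.0
) -> IntensityMap:
    """Maximum LGE intensity within ±``depth`` mm along each element normal.

    Sampling stations are spaced at half the smallest voxel size; values are
    interpolated trilinearly.  Elements whose centroid falls outside the
    volume get NaN and a warning.
    """
    if depth <= 0:
        raise ValueError("projection depth must be positive")
    step = float(lge.spacing.min()) / 2.0
    offsets = np.arange(-depth, depth + 1e-9, step)
    cent = mesh.centroids()
    normals = mesh.normals()
    # (m, s, 3) sample points
    pts = cent[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vox = lge.world_to_voxel(pts.reshape(-1, 3))
    shape = np.array(lge.data.shape)
    inside = np.all((vox >= -0.5) & (vox <= shape - 0.5), axis=1)
    samples = np.full(len(vox), -np.inf)
    if inside.any():
        samples[inside] = ndimage.map_coordinates(
            lge.data.astype(float), vox[inside].T, order=1, mode="nearest"
        )
    samples = samples.reshape(len(cent), len(offsets))
    values = samples.max(axis=1)
    cent_vox = lge.world_to_voxel(cent)
    cent_out = ~np.all((cent_vox >= -0.5) & (cent_vox <= shape - 0.5), axis=1)
    if cent_out.any():
        warnings.warn(f"{cent_out.sum()} element centroids outside the LGE volume; flagged NaN")
        values[cent_out] = np.nan
    values[np.isneginf(values)] = np.nan
    return IntensityMap(values=values, depth=depth)


def iir_threshold(lge: Volume, bloodpool_mask: Volume | np.ndarray, factor: float) -> float:
    """Image-intensity-ratio threshold: mean LGE over the bloodpool × factor."""
    mask = bloodpool_mask.data if isinstance(bloodpool_mask, Volume) else bloodpool_mask
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty bloodpool mask")
    return float(np.asarray(lge.data, dtype=float)[mask].mean() * factor)


def bloodpool_mask_from_body(body_mask: np.ndarray, erosion_voxels: int = 1) -> np.ndarray:
    """Erode the LA-body segmentation to avoid wall contamination of the mean."""
    mask = np.asarray(body_mask) > 0
    if erosion_voxels > 0:
        mask = ndimage.binary_erosion(mask, iterations=erosion_voxels)
    if not mask.any():
        raise ValueError("bloodpool mask empty after erosion")
    return mask


def fibrosis_score(
    imap: IntensityMap,
    mesh: LabelledSurfaceMesh,
    threshold: float,
    iir_factor: float = float("nan"),
) -> FibrosisSummary:
    """Area fraction of LA-body elements at/above the threshold.

    Pulmonary-vein and appendage elements are excluded; NaN-flagged elements
    are excluded from both numerator and denominator.
    """
    body = mesh.element_labels == STRUCTURE_LABELS["LA"]
    valid = body & np.isfinite(imap.values)
    if not valid.any():
        raise ValueError("no LA-body elements with valid intensity")
    areas = mesh.areas()
    hot = valid & (imap.values >= threshold)
    score = float(areas[hot].sum() / areas[valid].sum())
    norm = np.where(np.isfinite(imap.values), imap.values / threshold, np.nan)
    return FibrosisSummary(iir_factor=iir_factor, threshold=threshold, score=score, normalised=norm)
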