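"""3D scalar image volumes with physical (mm) geometry.

Voxel index ``(i, j, k)`` maps to world coordinates as
``world = origin + index * spacing`` (axis-aligned grids only, which is all
the phantom generator produces and all the pipeline needs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class ImageVolume:
    """A 3D scalar grid plus its voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three positive lengths (mm)")
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for an (N, 3) array of world points."""
        return (np.asarray(points_mm, dtype=float) - self.origin) / self.spacing

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def sample(self, points_mm: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Interpolate the volume at world points; outside the grid -> ``cval``."""
        pts = np.atleast_2d(points_mm)
        idx = self.world_to_index(pts)
        return map_coordinates(
            self.data.astype(float, copy=False), idx.T, order=order,
            mode="constant", cval=cval,
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def save(self, path: str) -> None:
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine), path)


def save_mask(mask: np.ndarray, like: ImageVolume, path: str) -> None:
    """Write a binary volume as uint8 NIfTI on the same grid as ``like``."""
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), like.affine), path)


def load_volume(path: str) -> ImageVolume:
    img = nib.load(path)
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing = np.diag(rot).copy()
    origin = aff[:3, 3].copy()
    data = np.asarray(img.dataobj)
    # fold negative spacings into a flip so spacing stays positive
    for ax in range(3):
        if spacing[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
            spacing[ax] = -spacing[ax]
    return ImageVolume(np.ascontiguousarray(data), spacing, origin)
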