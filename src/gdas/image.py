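"""3-D scalar images and binary segmentations on a voxel grid.

The affine maps voxel *indices* (i, j, k), taken at voxel centers, to
world coordinates in mm.  NIfTI files are read and written with nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["ScalarImage3D", "BinarySegmentation", "read_image", "write_image"]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=np.float64)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-300:
        raise ValueError("affine must be invertible")
    return affine


@dataclass
class ScalarImage3D:
    """Voxel intensities plus a voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3-D")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths (dx, dy, dz) in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(ijk)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """(N, 3) world coordinates of all voxel centers, C-order."""
        grid = np.indices(self.data.shape).reshape(3, -1).T
        return self.voxel_to_world(grid)

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Trilinear (order=1) interpolation of intensities at world points."""
        vox = self.world_to_voxel(points)
        return map_coordinates(self.data, vox.T, order=order, mode="nearest")


@dataclass
class BinarySegmentation:
    """Boolean voxel array on the same grid contract as :class:`ScalarImage3D`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("segmentation data must be 3-D")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return ScalarImage3D.world_to_voxel(self, points)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return ScalarImage3D.voxel_to_world(self, ijk)

    def as_image(self) -> ScalarImage3D:
        return ScalarImage3D(self.data.astype(np.float64), self.affine)

    def volume(self) -> float:
        """Foreground volume in mm^3."""
        return float(self.data.sum()) * self.voxel_volume


def read_image(path: str, binary: bool = False):
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if binary:
        return BinarySegmentation(data > 0.5, img.affine)
    return ScalarImage3D(data.astype(np.float64), img.affine)


def write_image(image: ScalarImage3D | BinarySegmentation, path: str) -> None:
    data = image.data.astype(np.uint8) if image.data.dtype == bool else image.data
    nib.save(nib.Nifti1Image(data, image.affine), path)
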