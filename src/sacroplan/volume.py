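"""Voxel volumes in Hounsfield units.

Coordinate convention: right-handed patient-space millimetres. Voxel index
``(i, j, k)`` (0-based, array axes = x, y, z) maps to world coordinates as
``origin + index * spacing``. NIfTI affines are built accordingly; only
axis-aligned, positively oriented volumes are produced or consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["CtVolume"]


@dataclass
class CtVolume:
    """A 3D scalar field of HU values on a regular axis-aligned grid.

    Parameters
    ----------
    voxels : (nx, ny, nz) float array of HU values.
    spacing : per-axis voxel edge length in mm.
    origin : world position in mm of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1D arrays of voxel-centre world coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]

    def sample_at(self, xyz: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of HU at world points (n, 3)."""
        from scipy.ndimage import map_coordinates

        idx = self.world_to_index(np.atleast_2d(xyz)).T
        return map_coordinates(self.voxels, idx, order=1, mode="nearest")

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
        path = Path(path)
        if path.suffix in {".mha", ".mhd"}:
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(np.ascontiguousarray(self.voxels.T))
            img.SetSpacing(tuple(self.spacing))
            img.SetOrigin(tuple(self.origin))
            sitk.WriteImage(img, str(path))
        else:
            nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), self.affine()), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "CtVolume":
        path = Path(path)
        if path.suffix in {".mha", ".mhd"}:
            import SimpleITK as sitk

            img = sitk.ReadImage(str(path))
            return cls(
                voxels=sitk.GetArrayFromImage(img).T,
                spacing=np.asarray(img.GetSpacing()),
                origin=np.asarray(img.GetOrigin()),
            )
        img = nib.load(str(path))
        aff = img.affine
        spacing = np.abs(np.diag(aff)[:3])
        return cls(voxels=np.asarray(img.dataobj, dtype=float), spacing=spacing, origin=aff[:3, 3])
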