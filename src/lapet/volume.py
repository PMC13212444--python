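"""Minimal 3-D volume container with a voxel-to-world affine.

Wraps the array + affine + optional brain mask triple that every
voxelwise operation in this package consumes, with NIfTI-1 round-trip
via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage"]


@dataclass
class VolumeImage:
    """A 3-D intensity grid with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data : (i, j, k) float array
        Voxel intensities.
    affine : (4, 4) array
        Homogeneous voxel-to-world map; must be invertible.
    mask : (i, j, k) bool array, optional
        In-brain voxels. Out-of-mask voxels are ignored by every
        statistic, never treated as zeros.
    is_scaled : bool
        True once the volume has been proportionally scaled to its
        global mean (SUVR).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None
    is_scaled: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray, **kw) -> "VolumeImage":
        """Copy carrying new data on the same grid."""
        return replace(self, data=np.asarray(data, dtype=float), **kw)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (homo @ self.affine.T)[:, :3]

    def in_mask_values(self) -> np.ndarray:
        """Flat vector of in-mask voxel values (all voxels if no mask)."""
        if self.mask is None:
            return self.data.ravel()
        return self.data[self.mask]

    # -- NIfTI I/O ---------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, mask: np.ndarray | None = None) -> "VolumeImage":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, mask=mask)
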