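"""Volumetric grids and coordinate conventions.

All spatial analysis in this package happens on a :class:`VolumeGrid`: a 3D
voxel lattice with a voxel-to-world affine (world coordinates in MNI
millimetres) and a boolean analysis mask.  Voxel indices are 0-based; all
distances are computed in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid with affine and analysis mask.

    Parameters
    ----------
    shape : tuple of 3 ints
        Grid dimensions in voxels.
    affine : (4, 4) ndarray
        Voxel-index -> world-mm map.  Must be invertible.
    mask : (shape) bool ndarray
        Analysis mask; must contain at least one True voxel.
    """

    shape: tuple
    affine: np.ndarray
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        if not mask.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "mask", mask)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def vox_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz

    def mm_to_vox(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of world points (not rounded)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def nearest_voxel(self, xyz) -> np.ndarray:
        return np.rint(self.mm_to_vox(xyz)).astype(int)

    def in_bounds(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        ok = np.ones(len(ijk), dtype=bool)
        for ax in range(3):
            ok &= (ijk[:, ax] >= 0) & (ijk[:, ax] < self.shape[ax])
        return ok

    def masked_mm(self) -> np.ndarray:
        """World coordinates (mm) of all masked voxel centers, in C order."""
        ijk = np.argwhere(self.mask)
        return self.vox_to_mm(ijk)

    def to_image(self, values=None) -> nib.Nifti1Image:
        """Wrap `values` (or the mask) as a NIfTI-1 image on this grid."""
        if values is None:
            data = self.mask.astype(np.uint8)
        else:
            data = np.asarray(values)
            if data.shape[:3] != self.shape:
                raise ValueError("values do not match grid shape")
        return nib.Nifti1Image(data, self.affine)


def mni_like_grid(shape=(40, 48, 40), voxel_mm=2.0, mask=None) -> VolumeGrid:
    """A 2 mm isotropic MNI-like grid centered on the origin.

    The affine follows the usual RAS convention with the world origin at the
    grid center, so coordinates behave like MNI mm.  Default mask is the full
    box; pass an explicit boolean array for anything else.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return VolumeGrid(shape=shape, affine=affine, mask=mask)


def ellipsoid_mask_grid(shape=(40, 48, 40), voxel_mm=2.0, margin_voxels=1) -> VolumeGrid:
    """An MNI-like grid whose mask is an inscribed ellipsoid (crude brain shape)."""
    grid = mni_like_grid(shape, voxel_mm)
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1) / 2.0
    semi = center - margin_voxels
    semi = np.maximum(semi, 1.0)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return VolumeGrid(shape=shape, affine=grid.affine, mask=r2 <= 1.0)


def grid_from_image(img: nib.Nifti1Image, mask_threshold=0.0) -> VolumeGrid:
    data = np.asarray(img.dataobj)
    if data.ndim == 4:
        data = data[..., 0]
    return VolumeGrid(shape=data.shape, affine=img.affine, mask=data > mask_threshold)


def sphere_voxels(grid: VolumeGrid, center_mm, radius_mm, restrict_mask=None) -> np.ndarray:
    """Indices (N, 3) of voxels whose centers lie within `radius_mm` of `center_mm`.

    Restricted to `restrict_mask` (default: the grid mask).
    """
    if restrict_mask is None:
        restrict_mask = grid.mask
    center_mm = np.asarray(center_mm, dtype=float)
    cv = grid.mm_to_vox(center_mm)[0]
    # conservative bounding box in voxel units
    span = np.ceil(radius_mm / grid.voxel_sizes).astype(int) + 1
    lo = np.maximum(np.floor(cv).astype(int) - span, 0)
    hi = np.minimum(np.ceil(cv).astype(int) + span + 1, grid.shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    ii, jj, kk = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ijk = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    xyz = grid.vox_to_mm(ijk)
    d2 = ((xyz - center_mm) ** 2).sum(axis=1)
    keep = d2 <= radius_mm ** 2
    ijk = ijk[keep]
    inmask = restrict_mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    return ijk[inmask]
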