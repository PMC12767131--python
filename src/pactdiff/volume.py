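"""Volumetric image container shared by the simulator and the restorer."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeImage", "joint_minmax_normalize"]


@dataclass
class VolumeImage:
    """3D scalar grid (nz, ny, nx) with voxel spacing and origin in mm.

    ``origin`` is the world coordinate (x, y, z) of the center of voxel
    (0, 0, 0); voxel index (iz, iy, ix) maps to world
    (origin_x + ix*dx, origin_y + iy*dy, origin_z + iz*dz).
    """

    voxels: np.ndarray
    voxel_spacing: tuple[float, float, float]  # (dz, dy, dx)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, z)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @classmethod
    def centered(cls, shape, spacing) -> "VolumeImage":
        """Empty grid whose center voxel sits at the world origin."""
        shape = tuple(int(s) for s in shape)
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        dz, dy, dx = (float(s) for s in spacing)
        nz, ny, nx = shape
        origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz)
        return cls(np.zeros(shape), (dz, dy, dx), origin)

    def world_coordinates(self) -> np.ndarray:
        """(nz, ny, nx, 3) array of per-voxel world (x, y, z) in mm."""
        nz, ny, nx = self.shape
        dz, dy, dx = self.voxel_spacing
        ox, oy, oz = self.origin
        z = oz + np.arange(nz) * dz
        y = oy + np.arange(ny) * dy
        x = ox + np.arange(nx) * dx
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def like(self, voxels: np.ndarray) -> "VolumeImage":
        return VolumeImage(voxels, self.voxel_spacing, self.origin)


def joint_minmax_normalize(a: np.ndarray, b: np.ndarray):
    """Min-max normalize two arrays with one shared scale (pairwise).

    Both outputs land in [0, 1] using the combined minimum and maximum, so a
    clean/degraded pair keeps a common intensity meaning.  A constant pair
    maps to zeros.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return np.zeros_like(a), np.zeros_like(b)
    return (a - lo) / (hi - lo), (b - lo) / (hi - lo)
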