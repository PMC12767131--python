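"""Synthetic optical-absorption phantoms.

The vascular phantom stands in for in-vivo vasculature: smooth branching
tubes with Gaussian radial intensity profiles on a dark background, fully
deterministic per seed.  It is tuned for plausibility of the reconstruction
problem (sparse bright curvilinear structures in a dark volume), not for
anatomical fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Phantom", "generate_vascular_phantom", "point_phantom"]


@dataclass(frozen=True)
class Phantom:
    """3D absorption map in [0, 1] with isotropic-per-axis voxel spacing (mm)."""

    absorption_map: np.ndarray  # (nz, ny, nx)
    voxel_spacing: tuple[float, float, float]
    seed: int | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.absorption_map.shape


def generate_vascular_phantom(
    grid_shape: tuple[int, int, int],
    voxel_spacing: float | tuple[float, float, float] = 0.2,
    n_branches: int = 6,
    seed: int = 0,
    background: float = 0.0,
) -> Phantom:
    """Grow ``n_branches`` random smooth tubes through the grid.

    Each branch is a correlated random walk; voxels receive intensity
    exp(-d^2 / (2 r^2)) from the nearest walk point, with per-branch radius
    r of 1-2 voxels and amplitude in [0.6, 1].  Values are clamped to [0, 1].
    n_branches = 0 yields a background-only map.
    """
    nz, ny, nx = (int(s) for s in grid_shape)
    if nz < 1 or ny < 1 or nx < 1:
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    if n_branches < 0:
        raise ValueError(f"n_branches must be >= 0, got {n_branches}")
    if np.isscalar(voxel_spacing):
        spacing = (float(voxel_spacing),) * 3
    else:
        spacing = tuple(float(s) for s in voxel_spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"voxel_spacing must be positive, got {spacing}")

    rng = np.random.default_rng(seed)
    vol = np.full((nz, ny, nx), float(background))
    shape_v = np.array([nz, ny, nx], dtype=float)
    for _ in range(n_branches):
        pos = rng.uniform(0.15, 0.85, size=3) * shape_v
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(1.0, 2.0)
        amp = rng.uniform(0.6, 1.0)
        n_steps = int(1.5 * max(ny, nx))
        pts = np.empty((n_steps, 3))
        for s in range(n_steps):
            pts[s] = pos
            direction += 0.25 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * 0.7
            # reflect at the walls to keep vessels inside
            for ax in range(3):
                if pos[ax] < 1 or pos[ax] > shape_v[ax] - 2:
                    direction[ax] *= -1.0
                    pos[ax] = np.clip(pos[ax], 1, shape_v[ax] - 2)
        _stamp_tube(vol, pts, radius, amp)
    np.clip(vol, 0.0, 1.0, out=vol)
    return Phantom(absorption_map=vol, voxel_spacing=spacing, seed=int(seed))


def _stamp_tube(vol: np.ndarray, pts: np.ndarray, radius: float, amp: float) -> None:
    """Deposit Gaussian cross-section intensity around each path point."""
    half = max(int(np.ceil(3 * radius)), 1)
    nz, ny, nx = vol.shape
    for p in pts:
        z0, y0, x0 = (int(round(c)) for c in p)
        zs = slice(max(z0 - half, 0), min(z0 + half + 1, nz))
        ys = slice(max(y0 - half, 0), min(y0 + half + 1, ny))
        xs = slice(max(x0 - half, 0), min(x0 + half + 1, nx))
        zz, yy, xx = np.meshgrid(
            np.arange(zs.start, zs.stop),
            np.arange(ys.start, ys.stop),
            np.arange(xs.start, xs.stop),
            indexing="ij",
        )
        d2 = (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
        contrib = amp * np.exp(-d2 / (2.0 * radius**2))
        np.maximum(vol[zs, ys, xs], contrib, out=vol[zs, ys, xs])


def point_phantom(
    grid_shape: tuple[int, int, int],
    voxel_index: tuple[int, int, int],
    voxel_spacing: float | tuple[float, float, float] = 0.2,
    amplitude: float = 1.0,
) -> Phantom:
    """Single-voxel absorber, the workhorse of PSF and localization checks."""
    vol = np.zeros(tuple(int(s) for s in grid_shape))
    vol[tuple(int(i) for i in voxel_index)] = float(amplitude)
    if np.isscalar(voxel_spacing):
        spacing = (float(voxel_spacing),) * 3
    else:
        spacing = tuple(float(s) for s in voxel_spacing)
    return Phantom(absorption_map=vol, voxel_spacing=spacing)
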