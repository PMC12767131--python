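"""Spectral unmixing of multi-wavelength photoacoustic volumes.

Each voxel's photoacoustic amplitude at wavelength lambda is modeled as
epsilon_HbO(lambda) * C_HbO + epsilon_HbR(lambda) * C_HbR; with >= 2
wavelengths the per-voxel concentrations follow from a linear least-squares
solve, after an optional 3x3x3 median prefilter and per-wavelength laser
power normalization.  Oxygen saturation and total hemoglobin derive as
sO2 = C_HbO / (C_HbO + C_HbR) and C_HbT = C_HbO + C_HbR, with sO2 masked
where HbT falls below a floor to avoid 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.ndimage import median_filter

__all__ = [
    "ExtinctionTable",
    "ChromophoreMaps",
    "lsq_unmix",
    "compute_so2_hbt",
    "load_default_extinction_table",
]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients (cm^-1 M^-1) of HbO and HbR per wavelength."""

    wavelengths_nm: np.ndarray
    epsilon: np.ndarray  # shape (n_wavelengths, 2), columns (HbO, HbR)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "epsilon", eps)
        if wl.shape[0] < 2:
            raise ValueError("need at least 2 wavelengths to unmix 2 chromophores")
        if eps.shape != (wl.shape[0], 2):
            raise ValueError(f"epsilon must be ({wl.shape[0]}, 2), got {eps.shape}")
        if np.linalg.matrix_rank(eps) < 2:
            raise ValueError("extinction matrix is rank-deficient (proportional spectra)")

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(
            wavelengths_nm=np.atleast_1d(data["wavelength_nm"]),
            epsilon=np.column_stack(
                [np.atleast_1d(data["eps_hbo"]), np.atleast_1d(data["eps_hbr"])]
            ),
        )


def load_default_extinction_table() -> ExtinctionTable:
    """Hemoglobin extinction at 730/756/796/866 nm from a standard compilation."""
    ref = resources.files("pactdiff.data") / "extinction_hb.csv"
    with resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


@dataclass
class ChromophoreMaps:
    """Per-voxel HbO/HbR concentrations and derived sO2 / total hemoglobin.

    ``valid`` marks voxels where sO2 is defined (HbT above floor and the
    least-squares solution non-degenerate); sO2 is NaN elsewhere.
    """

    c_hbo: np.ndarray
    c_hbr: np.ndarray
    so2: np.ndarray | None = None
    c_hbt: np.ndarray | None = None
    valid: np.ndarray | None = None
    clamped: np.ndarray | None = field(default=None, repr=False)


def lsq_unmix(
    volumes: list[np.ndarray],
    table: ExtinctionTable,
    laser_powers: list[float] | None = None,
    prefilter: bool = True,
) -> ChromophoreMaps:
    """Per-voxel least-squares unmixing of HbO/HbR from multi-wavelength volumes.

    Volumes must be co-registered on one grid, ordered as ``table.wavelengths_nm``.
    Each is optionally median-filtered (3x3x3) and divided by its laser power,
    then the overdetermined system epsilon @ C = PA is solved voxelwise.
    Negative concentrations are clamped to zero and flagged in ``clamped``.
    """
    n_wl = table.epsilon.shape[0]
    if len(volumes) != n_wl:
        raise ValueError(f"got {len(volumes)} volumes for {n_wl} table wavelengths")
    if laser_powers is not None and len(laser_powers) != n_wl:
        raise ValueError("laser_powers length must match the wavelength count")
    vols = [np.asarray(v, dtype=float) for v in volumes]
    shape = vols[0].shape
    if any(v.shape != shape for v in vols):
        raise ValueError("all volumes must share one grid shape")
    proc = []
    for k, v in enumerate(vols):
        if prefilter:
            v = median_filter(v, size=3)
        if laser_powers is not None:
            p = float(laser_powers[k])
            if p <= 0:
                raise ValueError(f"laser power must be positive, got {p}")
            v = v / p
        proc.append(v.ravel())
    pa = np.stack(proc, axis=0)  # (n_wl, n_voxels)
    # one pseudo-inverse serves every voxel: the design matrix is shared
    sol = np.linalg.lstsq(table.epsilon, pa, rcond=None)[0]  # (2, n_voxels)
    clamped = sol < 0
    sol = np.clip(sol, 0.0, None)
    return ChromophoreMaps(
        c_hbo=sol[0].reshape(shape),
        c_hbr=sol[1].reshape(shape),
        clamped=np.any(clamped, axis=0).reshape(shape),
    )


def compute_so2_hbt(maps: ChromophoreMaps, hbt_floor: float | None = None) -> ChromophoreMaps:
    """Fill sO2 = HbO/(HbO+HbR) and HbT = HbO+HbR on ``maps`` in place.

    Voxels with HbT <= ``hbt_floor`` (default: 1% of the max HbT) are masked
    invalid and get sO2 = NaN.  Returns ``maps`` for chaining.
    """
    hbo = np.asarray(maps.c_hbo, dtype=float)
    hbr = np.asarray(maps.c_hbr, dtype=float)
    if np.any(hbo < 0) or np.any(hbr < 0):
        raise ValueError("concentrations must be non-negative")
    hbt = hbo + hbr
    if hbt_floor is None:
        hbt_floor = 0.01 * float(hbt.max()) if hbt.size else 0.0
    valid = hbt > hbt_floor
    so2 = np.full(hbt.shape, np.nan)
    np.divide(hbo, hbt, out=so2, where=valid)
    maps.so2 = so2
    maps.c_hbt = hbt
    maps.valid = valid
    return maps
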