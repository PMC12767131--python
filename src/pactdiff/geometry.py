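"""Hemispherical transducer-array geometry.

Elements are laid out on a Fermat spiral running from the pole of the
hemisphere outward to its rim.  This single ordering gives both subsampling
regimes their physical character: a contiguous index prefix 1..k forms a
spatially compact cap around the pole (a small aperture, hence blur), while
a stride-4 subset 1, 5, 9, ... remains quasi-uniform over the whole dome
(a sparse aperture, hence streaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArrayGeometry", "build_hemisphere_geometry"]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class ArrayGeometry:
    """Positions (mm) of transducer elements on a hemisphere (z >= 0).

    ``element_positions[k]`` is the position of element number k+1: element
    numbering is exposed 1-based so the sparse-scheme formula "4i+1" reads
    exactly as published.
    """

    element_positions: np.ndarray  # (N, 3) mm
    radius: float

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    def positions_of(self, indices_1based) -> np.ndarray:
        idx = np.asarray(indices_1based, dtype=int)
        if idx.min() < 1 or idx.max() > self.n_elements:
            raise ValueError("element indices out of range")
        return self.element_positions[idx - 1]

    def polar_angles(self) -> np.ndarray:
        """Polar angle from the +z pole for every element, radians."""
        z = self.element_positions[:, 2]
        return np.arccos(np.clip(z / self.radius, -1.0, 1.0))


def build_hemisphere_geometry(
    n_elements: int, radius: float, ordering: str = "spiral"
) -> ArrayGeometry:
    """Place ``n_elements`` on a hemisphere of ``radius`` mm, spiral-ordered.

    Element k (1-based) sits at z_k = radius * (1 - (k - 1/2)/N) — uniform in
    z, hence uniform in area on the sphere — with azimuth advancing by the
    golden angle, so consecutive indices wind outward from the pole.
    """
    if n_elements < 1:
        raise ValueError(f"n_elements must be >= 1, got {n_elements}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if ordering != "spiral":
        raise ValueError(f"unknown ordering {ordering!r}")
    k = np.arange(1, n_elements + 1, dtype=float)
    z = radius * (1.0 - (k - 0.5) / n_elements)
    rho = np.sqrt(np.maximum(radius**2 - z**2, 0.0))
    phi = k * _GOLDEN_ANGLE
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return ArrayGeometry(element_positions=pos, radius=float(radius))
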