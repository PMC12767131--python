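"""Vessel quantification and projections for functional PACT maps."""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["vessel_density", "max_projection"]


def vessel_density(
    hbt_map: np.ndarray,
    roi: np.ndarray,
    threshold_rule: str | float = "otsu",
):
    """Segment vessels inside an ROI and quantify them.

    Returns ``(density, mean_hbt)`` where density = vessel area / ROI area
    and mean_hbt is the mean map value over segmented vessel voxels (NaN if
    nothing is segmented).  ``threshold_rule`` is "otsu" (threshold from the
    ROI histogram) or a float in (0, 1) interpreted as a quantile of the ROI
    values.  Voxels strictly above the threshold count as vessel.
    """
    hbt_map = np.asarray(hbt_map, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != hbt_map.shape:
        raise ValueError(f"roi shape {roi.shape} != map shape {hbt_map.shape}")
    vals = hbt_map[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    if threshold_rule == "otsu":
        if np.ptp(vals) == 0:
            thr = vals[0] - 1.0  # uniform ROI: everything counts as vessel
        else:
            thr = float(threshold_otsu(vals))
    elif isinstance(threshold_rule, (int, float)):
        q = float(threshold_rule)
        if not 0.0 < q < 1.0:
            raise ValueError(f"quantile threshold must lie in (0,1), got {q}")
        thr = float(np.quantile(vals, q))
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    vessel = vals > thr
    density = float(vessel.mean())
    mean_hbt = float(vals[vessel].mean()) if vessel.any() else float("nan")
    return density, mean_hbt


def max_projection(volume: np.ndarray, axis: int = 0, mode: str = "map"):
    """Maximum amplitude projection along one axis.

    mode="map" returns the per-pixel maximum; mode="depth_encoded" returns
    ``(map, depth_index)`` where depth_index is the argmax along the axis
    (ties resolved to the shallowest index), ready for hue encoding.
    """
    volume = np.asarray(volume, dtype=float)
    if not -volume.ndim <= axis < volume.ndim:
        raise ValueError(f"axis {axis} invalid for ndim {volume.ndim}")
    mip = volume.max(axis=axis)
    if mode == "map":
        return mip
    if mode == "depth_encoded":
        return mip, volume.argmax(axis=axis)
    raise ValueError(f"unknown projection mode {mode!r}")
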