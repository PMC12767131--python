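"""Delay-and-sum volumetric reconstruction."""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import hilbert

from .geometry import ArrayGeometry
from .simulate import RFFrame
from .volume import VolumeImage

__all__ = ["das_reconstruct"]

logger = logging.getLogger(__name__)


def das_reconstruct(
    frame: RFFrame,
    geometry: ArrayGeometry,
    grid: VolumeImage,
    envelope: bool = False,
) -> VolumeImage:
    """Delay-and-sum: back-project each channel onto the grid and sum.

    Every voxel receives, from every channel, the sample at delay
    ||p_elem - p_voxel|| / c (linear interpolation between samples; delays
    outside the recorded window contribute zero and are warned about once).
    The channel sum is divided by the channel count so reconstructions from
    different aperture subsets share one intensity scale.  The map is linear
    in the RF frame.  With ``envelope=True`` the summed volume is
    envelope-detected (Hilbert magnitude) along the depth axis.
    """
    coords = grid.world_coordinates().reshape(-1, 3)  # (n_vox, 3) world xyz
    positions = geometry.positions_of(frame.indices_1based())
    fs_per_us = frame.sampling_rate * 1e-6
    n_t = frame.samples.shape[1]
    sample_axis = np.arange(n_t, dtype=float)
    acc = np.zeros(coords.shape[0])
    any_outside = False
    for ch in range(frame.n_channels):
        dist = np.linalg.norm(coords - positions[ch], axis=1)
        s = dist / frame.speed_of_sound * fs_per_us - frame.t0 * frame.sampling_rate
        if not any_outside and (s.min() < 0 or s.max() > n_t - 1):
            any_outside = True
        acc += np.interp(s, sample_axis, frame.samples[ch], left=0.0, right=0.0)
    if any_outside:
        logger.warning(
            "some voxels fall outside the recorded time window; "
            "their contributions were zeroed"
        )
    vol = (acc / frame.n_channels).reshape(grid.shape)
    if envelope:
        vol = np.abs(hilbert(vol, axis=0))
    return grid.like(vol)
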