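"""Forward acoustic simulation: phantom -> per-element RF time series.

Each absorbing voxel emits a band-limited bipolar wavelet (Gaussian-modulated
sinusoid at the transducer center frequency, envelope width set by the
fractional bandwidth) that reaches element e after a time of flight
||p_e - p_v|| / c, attenuated by 1/distance; contributions superpose
linearly.  The simulation deposits each voxel's amplitude at its fractional
delay bin and convolves every channel once with the wavelet, which is
exactly the linear superposition model evaluated efficiently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, gausspulse

from .geometry import ArrayGeometry
from .phantom import Phantom

__all__ = ["RFFrame", "SubsampleScheme", "simulate_pa_rf", "select_elements"]


@dataclass
class RFFrame:
    """Per-element pressure time series.

    samples          : (n_channels, n_time), arbitrary pressure units.
    sampling_rate    : Hz.
    speed_of_sound   : mm/us.
    t0               : time of sample 0, seconds.
    element_indices  : 1-based element numbers of the rows (None = 1..N).
    """

    samples: np.ndarray
    sampling_rate: float
    speed_of_sound: float
    t0: float = 0.0
    element_indices: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (channels, time)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.element_indices is not None:
            self.element_indices = np.asarray(self.element_indices, dtype=int)
            if self.element_indices.shape[0] != self.samples.shape[0]:
                raise ValueError("element_indices must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def indices_1based(self) -> np.ndarray:
        if self.element_indices is None:
            return np.arange(1, self.n_channels + 1)
        return self.element_indices


def _wavelet_kernel(sampling_rate: float, center_freq: float, bw: float):
    """Sampled transducer wavelet and the index of its peak (t = 0)."""
    # envelope support: gausspulse's cutoff time at -60 dB envelope
    t_cut = gausspulse("cutoff", fc=center_freq, bw=bw, tpr=-60)
    n_half = int(np.ceil(t_cut * sampling_rate)) + 1
    t = np.arange(-n_half, n_half + 1) / sampling_rate
    return gausspulse(t, fc=center_freq, bw=bw), n_half


def simulate_pa_rf(
    phantom: Phantom,
    geometry: ArrayGeometry,
    sampling_rate: float = 40e6,
    center_freq: float = 2.02e6,
    fractional_bandwidth: float = 0.54,
    speed_of_sound: float = 1.5,
    t0: float = 0.0,
) -> RFFrame:
    """Simulate the photoacoustic RF frame for a phantom centered at origin.

    The phantom grid is centered on the world origin (the hemisphere's
    center of curvature); geometry positions are in the same frame.
    ``sampling_rate`` must exceed twice the wavelet's top frequency
    2 * center_freq * (1 + fractional_bandwidth).
    """
    nyquist_needed = 2.0 * center_freq * (1.0 + fractional_bandwidth)
    if sampling_rate <= nyquist_needed:
        raise ValueError(
            f"sampling_rate {sampling_rate:g} Hz undersamples the wavelet "
            f"(needs > {nyquist_needed:g} Hz)"
        )
    vol = phantom.absorption_map
    dz, dy, dx = phantom.voxel_spacing
    nz, ny, nx = vol.shape
    iz, iy, ix = np.nonzero(vol)
    amps = vol[iz, iy, ix]
    # world coordinates of active voxels, grid centered at origin
    px = (ix - (nx - 1) / 2) * dx
    py = (iy - (ny - 1) / 2) * dy
    pz = (iz - (nz - 1) / 2) * dz
    pts = np.column_stack([px, py, pz])  # (n_active, 3)

    fs_per_us = sampling_rate * 1e-6  # samples per microsecond
    half_diag = 0.5 * np.linalg.norm([nz * dz, ny * dy, nx * dx])
    max_dist = geometry.radius + half_diag
    n_t = int(np.ceil(max_dist / speed_of_sound * fs_per_us)) + 4

    kernel, n_half = _wavelet_kernel(sampling_rate, center_freq, fractional_bandwidth)
    impulses = np.zeros((geometry.n_elements, n_t + 1))
    if pts.shape[0] > 0:
        for ch, epos in enumerate(geometry.element_positions):
            dist = np.linalg.norm(pts - epos, axis=1)
            dist = np.maximum(dist, 1e-6)
            s = dist / speed_of_sound * fs_per_us - t0 * sampling_rate
            i0 = np.floor(s).astype(int)
            frac = s - i0
            ok = (i0 >= 0) & (i0 < n_t)
            a = amps[ok] / dist[ok]
            np.add.at(impulses[ch], i0[ok], a * (1.0 - frac[ok]))
            np.add.at(impulses[ch], i0[ok] + 1, a * frac[ok])
    full = fftconvolve(impulses, kernel[None, :], mode="full")
    samples = full[:, n_half : n_half + n_t]
    return RFFrame(
        samples=samples,
        sampling_rate=sampling_rate,
        speed_of_sound=speed_of_sound,
        t0=t0,
    )


@dataclass(frozen=True)
class SubsampleScheme:
    """Element-retention scheme.

    mode="sparse" keeps elements {start + stride*i : i = 0..count-1}
    (defaults stride 4, start 1, i.e., the "4i+1" elements); mode="cluster"
    keeps the contiguous block start..start+count-1 (default start 1).
    """

    mode: str
    count: int
    stride: int = 4
    start: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("sparse", "cluster"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.stride < 1 or self.start < 1:
            raise ValueError("stride and start must be >= 1")

    def retained_indices(self, n_elements: int) -> np.ndarray:
        """1-based element numbers retained under this scheme."""
        if self.mode == "sparse":
            idx = self.start + self.stride * np.arange(self.count)
        else:
            idx = self.start + np.arange(self.count)
        if idx[-1] > n_elements:
            raise ValueError(
                f"scheme needs element {idx[-1]} but array has {n_elements}"
            )
        return idx

    @property
    def name(self) -> str:
        return f"{self.mode}{self.count}"


def select_elements(
    frame: RFFrame, geometry: ArrayGeometry, scheme: SubsampleScheme
) -> RFFrame:
    """Keep only the channels a subsampling scheme retains, order preserved."""
    if frame.n_channels != geometry.n_elements:
        raise ValueError(
            f"frame has {frame.n_channels} channels but geometry has "
            f"{geometry.n_elements} elements"
        )
    idx = scheme.retained_indices(geometry.n_elements)
    return RFFrame(
        samples=frame.samples[idx - 1],
        sampling_rate=frame.sampling_rate,
        speed_of_sound=frame.speed_of_sound,
        t0=frame.t0,
        element_indices=idx,
    )
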