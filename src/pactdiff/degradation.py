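"""Gabor-filter degradation operator and the deterministic diffusion process.

The forward ("cold" diffusion) process interpolates between a clean slice
``x0`` and its degraded counterpart ``xT`` through a frequency-selective
linear operator ``G`` built from a Gabor filter:

    x_t = D(x0, xT, t) = alpha_t * G(x0) + (x_T - alpha_t * G(x_T))
        = x_T + alpha_t * G(x0 - x_T)

with ``alpha_t`` decreasing linearly from 0.999 at t=1 to 0 at t=T.  Because
``G`` acts pointwise in its diagonalizing domain (the 2D Fourier domain by
default), the forward map can be inverted pointwise, which is what the
sampling-time endpoint estimate and renoising correction exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaborParams",
    "DegradationOperator",
    "DiffusionSchedule",
    "gabor_value",
    "build_operator",
    "alpha_schedule",
    "forward_degrade",
    "estimate_endpoint",
    "renoise_step",
]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of the Gabor filter G(i, j; theta, lam, sigma, psi, gamma).

    theta : orientation of the sinusoidal carrier, radians.
    lam   : carrier wavelength, pixels (or frequency bins in frequency mode).
    sigma : Gaussian envelope standard deviation, pixels.
    psi   : carrier phase offset, radians.
    gamma : envelope ellipticity (1 = isotropic).
    """

    theta: float = np.pi / 4
    lam: float = 3.3
    sigma: float = 10.0
    psi: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def gabor_value(params: GaborParams, i, j):
    """Evaluate the Gabor filter at coordinates (i, j).

    G = exp(-(i'^2 + gamma^2 j'^2) / (2 sigma^2)) * cos(2 pi i' / lam + psi)
    with i' = i cos(theta) + j sin(theta), j' = -i sin(theta) + j cos(theta).
    Accepts scalars or arrays (broadcast).
    """
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    ct, st = np.cos(params.theta), np.sin(params.theta)
    ip = i * ct + j * st
    jp = -i * st + j * ct
    envelope = np.exp(-(ip**2 + params.gamma**2 * jp**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * np.pi * ip / params.lam + params.psi)
    out = envelope * carrier
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DegradationOperator:
    """Linear operator applying a Gabor mask in image or frequency space.

    mask        : 2D array of Gabor values, |mask| <= 1.
    domain_mode : "frequency_mask" multiplies the centered 2D spectrum
                  pointwise (then inverse FFT, real part); "spatial_mask"
                  multiplies pixelwise in image space.
    """

    mask: np.ndarray
    domain_mode: str = "frequency_mask"

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Apply G to a 2D slice (linear, same shape out)."""
        x = np.asarray(x, dtype=float)
        if x.shape != self.mask.shape:
            raise ValueError(
                f"slice shape {x.shape} does not match operator shape {self.mask.shape}"
            )
        if self.domain_mode == "spatial_mask":
            return self.mask * x
        spec = np.fft.fftshift(np.fft.fft2(x))
        return np.fft.ifft2(np.fft.ifftshift(self.mask * spec)).real

    def to_transfer(self, x: np.ndarray) -> np.ndarray:
        """Map a slice into the operator's diagonalizing domain."""
        if self.domain_mode == "spatial_mask":
            return np.asarray(x, dtype=float)
        return np.fft.fftshift(np.fft.fft2(x))

    def from_transfer(self, z: np.ndarray) -> np.ndarray:
        if self.domain_mode == "spatial_mask":
            return np.asarray(z, dtype=float)
        return np.fft.ifft2(np.fft.ifftshift(z)).real


def build_operator(
    params: GaborParams,
    shape: tuple[int, int],
    domain_mode: str = "frequency_mask",
) -> DegradationOperator:
    """Evaluate the Gabor filter on a grid centered at the array midpoint.

    Coordinates run over pixel (or frequency-bin) offsets from the center
    ``floor(n/2)`` of each axis, matching the fftshifted spectrum layout in
    frequency mode.  In frequency mode the mask is symmetrized under
    frequency negation (G(k) + G(-k))/2, which makes the filter zero-phase:
    applying it to a real slice is then exactly a pointwise spectral
    multiplication, so the forward process inverts pointwise without any
    leakage through the discarded imaginary part.
    """
    if domain_mode not in ("frequency_mask", "spatial_mask"):
        raise ValueError(f"unknown domain_mode {domain_mode!r}")
    h, w = int(shape[0]), int(shape[1])
    if h < 2 or w < 2:
        raise ValueError(f"shape must be at least 2x2, got {shape}")
    ii = np.arange(h) - h // 2
    jj = np.arange(w) - w // 2
    mask = gabor_value(params, ii[:, None], jj[None, :])
    if domain_mode == "frequency_mask":
        # index of -k in the fftshifted layout (Nyquist bin is its own mirror)
        flip_i = (2 * (h // 2) - np.arange(h)) % h
        flip_j = (2 * (w // 2) - np.arange(w)) % w
        mask = 0.5 * (mask + mask[np.ix_(flip_i, flip_j)])
    return DegradationOperator(mask=mask, domain_mode=domain_mode)


@dataclass(frozen=True)
class DiffusionSchedule:
    """Linear alpha schedule: alpha_t = 0.999 (T - t) / (T - 1), t = 1..T."""

    T: int
    alphas: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def alpha(self, t: int) -> float:
        if not 1 <= t <= self.T:
            raise ValueError(f"step t={t} outside schedule 1..{self.T}")
        return float(self.alphas[t - 1])


def alpha_schedule(T: int) -> DiffusionSchedule:
    if T < 2:
        raise ValueError(f"schedule needs T >= 2, got {T}")
    t = np.arange(1, T + 1, dtype=float)
    alphas = 0.999 * (T - t) / (T - 1)
    return DiffusionSchedule(T=int(T), alphas=alphas)


def forward_degrade(
    x0: np.ndarray,
    xT: np.ndarray,
    t: int,
    op: DegradationOperator,
    sched: DiffusionSchedule,
) -> np.ndarray:
    """Forward process D(x0, xT, t) = x_T + alpha_t * G(x0 - x_T).

    At t = T (alpha = 0) this returns ``xT`` bit-exactly.
    """
    x0 = np.asarray(x0, dtype=float)
    xT = np.asarray(xT, dtype=float)
    if x0.shape != xT.shape or x0.shape != op.shape:
        raise ValueError(
            f"shape mismatch: x0 {x0.shape}, xT {xT.shape}, operator {op.shape}"
        )
    a = sched.alpha(t)
    if a == 0.0:
        return xT.copy()
    return xT + a * op.apply(x0 - xT)


def estimate_endpoint(
    xt: np.ndarray,
    x0_hat: np.ndarray,
    t: int,
    op: DegradationOperator,
    sched: DiffusionSchedule,
    guard_eps: float = 1e-3,
) -> np.ndarray:
    """Estimate the degraded endpoint: x̂_T = (x_t - alpha_t G x̂_0) / (1 - alpha_t G).

    The division is pointwise in the operator's diagonalizing domain.  Where
    |1 - alpha_t * g| < guard_eps the divisor is clamped (sign-preserving) so
    the output stays finite.
    """
    xt = np.asarray(xt, dtype=float)
    x0_hat = np.asarray(x0_hat, dtype=float)
    a = sched.alpha(t)
    if a == 0.0:
        return xt.copy()
    zt = op.to_transfer(xt)
    z0 = op.to_transfer(x0_hat)
    denom = 1.0 - a * op.mask
    small = np.abs(denom) < guard_eps
    denom = np.where(small, np.where(denom >= 0, guard_eps, -guard_eps), denom)
    return op.from_transfer((zt - a * op.mask * z0) / denom)


def renoise_step(
    xt: np.ndarray,
    x0_hat: np.ndarray,
    xt_hat: np.ndarray,
    t: int,
    op: DegradationOperator,
    sched: DiffusionSchedule,
) -> np.ndarray:
    """Corrected reverse step: x̂_{t-1} = x_t - D(x̂0, x̂_t, t) + D(x̂0, x̂_t, t-1).

    Re-degrading the endpoint estimate at both t and t-1 cancels the
    restorer's own error instead of letting it accumulate across steps.
    Requires t >= 2 so the forward process is never evaluated at step 0.
    """
    if t < 2:
        raise ValueError(f"renoise_step needs t >= 2, got {t}")
    xt = np.asarray(xt, dtype=float)
    d_t = forward_degrade(x0_hat, xt_hat, t, op, sched)
    d_tm1 = forward_degrade(x0_hat, xt_hat, t - 1, op, sched)
    return xt - d_t + d_tm1
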