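"""Linear state-space sequence model reference operations.

A continuous SSM  x'(t) = A x(t) + B u(t),  y(t) = C x(t)  is discretized by
zero-order hold (ZOH):

    Abar = exp(dt A)
    Bbar = (dt A)^{-1} (exp(dt A) - I) dt B     (-> dt B as A -> 0)

after which the sequence map can be computed either as a linear recurrence
x_k = Abar x_{k-1} + Bbar u_k, y_k = C x_k, or equivalently as a causal
convolution of u with the kernel K = (C Bbar, C Abar Bbar, ..., C Abar^{L-1} Bbar).
These NumPy reference implementations back the SSM refiner inside the
restoration network and serve as its oracle in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = ["SSMParams", "ssm_discretize", "ssm_recurrence", "ssm_convolution"]


def ssm_discretize(A: np.ndarray, B: np.ndarray, delta: float):
    """Zero-order-hold discretization of (A, B) with step size delta.

    Returns (Abar, Bbar) with Abar = exp(dt A) and
    Bbar = (dt A)^{-1}(exp(dt A) - I) dt B.  Computed through the block
    exponential exp([[dt A, dt B], [0, 0]]) = [[Abar, Bbar], [0, I]], which
    evaluates the integral form of Bbar without inverting dt A and therefore
    covers singular A and the limit Bbar -> dt B as A -> 0 exactly.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float)
    if B.ndim == 0:
        B = B.reshape(1, 1)
    elif B.ndim == 1:
        B = B[:, None]
    n, m = A.shape[0], B.shape[1]
    M = np.zeros((n + m, n + m))
    M[:n, :n] = delta * A
    M[:n, n:] = delta * B
    E = expm(M)
    return E[:n, :n], E[:n, n:]


@dataclass
class SSMParams:
    """Continuous and ZOH-discretized state-space parameters."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: float
    Abar: np.ndarray = None  # type: ignore[assignment]
    Bbar: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        B = np.asarray(self.B, dtype=float)
        self.B = B.reshape(-1, 1) if B.ndim <= 1 else B
        C = np.asarray(self.C, dtype=float)
        self.C = C.reshape(1, -1) if C.ndim <= 1 else C
        if self.Abar is None or self.Bbar is None:
            self.Abar, self.Bbar = ssm_discretize(self.A, self.B, self.delta)


def ssm_recurrence(params: SSMParams, u: np.ndarray) -> np.ndarray:
    """Run the discrete recurrence x_k = Abar x_{k-1} + Bbar u_k, y_k = C x_k.

    The state starts at zero; u is a length-L sequence of scalars.
    """
    u = np.asarray(u, dtype=float).ravel()
    n = params.Abar.shape[0]
    x = np.zeros((n, 1))
    y = np.empty(u.shape[0])
    for k, uk in enumerate(u):
        x = params.Abar @ x + params.Bbar * uk
        y[k] = (params.C @ x)[0, 0]
    return y


def ssm_kernel(params: SSMParams, L: int) -> np.ndarray:
    """Impulse-response kernel K = (C Bbar, C Abar Bbar, ..., C Abar^{L-1} Bbar)."""
    k = np.empty(L)
    v = params.Bbar.copy()
    for i in range(L):
        k[i] = (params.C @ v)[0, 0]
        v = params.Abar @ v
    return k


def ssm_convolution(params: SSMParams, u: np.ndarray) -> np.ndarray:
    """Compute the SSM output as the causal convolution u * K."""
    u = np.asarray(u, dtype=float).ravel()
    k = ssm_kernel(params, u.shape[0])
    return np.convolve(u, k)[: u.shape[0]]
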