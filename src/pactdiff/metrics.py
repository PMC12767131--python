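"""Image-quality metrics: PSNR and SSIM.

PSNR follows the standard definition 10 log10(MAX^2 / MSE) with MAX = 1 for
the [0, 1]-normalized volumes this package produces.  SSIM is provided in
two modes: the global-statistics form (one mean/variance/covariance per
image, the tested contract) and a windowed mode delegated to scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

__all__ = ["MetricReport", "psnr", "ssim", "evaluate_pair"]


def psnr(x: np.ndarray, y: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; returns +inf when x == y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_value**2 / mse)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    max_value: float = 1.0,
    C1: float | None = None,
    C2: float | None = None,
    mode: str = "global",
) -> float:
    """Structural similarity index.

    mode="global" uses one set of statistics over the whole image:
        SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
             / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))
    mode="windowed" computes the conventional sliding-window mean via
    scikit-image.  Defaults C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if C1 is None:
        C1 = (0.01 * max_value) ** 2
    if C2 is None:
        C2 = (0.03 * max_value) ** 2
    if C1 <= 0 or C2 <= 0:
        raise ValueError("C1 and C2 must be positive")
    if mode == "windowed":
        return float(_skimage_ssim(x, y, data_range=max_value))
    if mode != "global":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    mx, my = x.mean(), y.mean()
    vx = x.var()
    vy = y.var()
    cov = float(np.mean((x - mx) * (y - my)))
    num = (2 * mx * my + C1) * (2 * cov + C2)
    den = (mx**2 + my**2 + C1) * (vx + vy + C2)
    return float(num / den)


@dataclass
class MetricReport:
    """PSNR/SSIM for a volume pair with a per-slice breakdown (axis 0)."""

    psnr: float
    ssim: float
    per_slice: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim, "per_slice": self.per_slice}


def evaluate_pair(
    pred: np.ndarray, ref: np.ndarray, max_value: float = 1.0
) -> MetricReport:
    """Volume-level PSNR/SSIM plus a per-slice breakdown along axis 0."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    slices = []
    if pred.ndim == 3:
        for k in range(pred.shape[0]):
            slices.append(
                {
                    "slice": k,
                    "psnr": psnr(pred[k], ref[k], max_value),
                    "ssim": ssim(pred[k], ref[k], max_value),
                }
            )
    return MetricReport(
        psnr=psnr(pred, ref, max_value),
        ssim=ssim(pred, ref, max_value),
        per_slice=slices,
    )
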