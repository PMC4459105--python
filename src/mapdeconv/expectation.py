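"""Kernel-regression estimate of the nonstationary prior expectation E(f_s).

The MAP prior models the true image f as Gaussian with a spatially varying
mean E(f_s). Instead of freezing that mean at the measured image g (the
MAP-Hunt choice, unreliable at low SNR), it is re-estimated from the current
deconvolution iterate at every iteration as a kernel-weighted local mean:

    E_hat(f_s) = sum_{i in W_s} K(f_s, f_i) f_i / sum_{i in W_s} K(f_s, f_i)

with the Gaussian photometric kernel K(a, b) = exp(-(a - b)^2 / beta) and
W_s the (2r+1)^2 window centered at s. Samples whose intensity resembles the
center's dominate the average, so edges are preserved where a plain moving
average would blur them; beta sets the intensity scale of "resembles". As
beta -> infinity every weight tends to 1 and the estimate reduces to a box
mean.

The window is completed at image borders by reflection, and the center
sample always contributes weight exactly 1, so the denominator never
vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelConfig", "kernel_weight", "estimate_expectation"]


@dataclass(frozen=True)
class KernelConfig:
    """Parameters of the kernel-regression expectation estimator.

    beta: kernel relaxation parameter, in squared units of the intensity
        scale of the plane being processed (beta = 625 on a 0-255 scale
        corresponds to a soft intensity threshold of 25 levels).
    window_radius: half-width r of the square window W_s; the window holds
        (2r+1)^2 samples, so r = 4 gives the 81-sample window.
    """

    beta: float
    window_radius: int = 4

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


def kernel_weight(a, b, beta: float):
    """Gaussian photometric kernel K(a, b) = exp(-(a - b)^2 / beta).

    Symmetric, equal to 1 iff a == b, strictly decreasing in |a - b|.
    """
    if not beta > 0:
        raise ValueError("beta must be > 0")
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d = a - b
    return np.exp(-(d * d) / beta)


def estimate_expectation(f_current: np.ndarray, cfg: KernelConfig) -> np.ndarray:
    """Kernel-weighted local mean of the current iterate at every pixel.

    Returns a plane of the same shape. The output at each site is a convex
    combination of the window samples, hence bounded by the window min and
    max; a constant plane maps to itself.
    """
    f = np.asarray(f_current, dtype=np.float64)
    if f.ndim != 2 or f.size == 0:
        raise ValueError("f_current must be a non-empty 2-D plane")
    r = cfg.window_radius
    if 2 * r + 1 > min(f.shape):
        raise ValueError(
            f"window side {2 * r + 1} exceeds image extent {min(f.shape)}"
        )
    beta = float(cfg.beta)
    # half-sample reflection, matching scipy.ndimage's "reflect" convention
    padded = np.pad(f, r, mode="symmetric")
    h, w = f.shape
    num = np.zeros_like(f)
    den = np.zeros_like(f)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            fi = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            d = f - fi
            weight = np.exp(-(d * d) / beta)
            num += weight * fi
            den += weight
    return num / den
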