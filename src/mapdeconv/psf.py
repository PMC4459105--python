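"""Point-spread functions: construction, normalization, adjoint, application.

The PSF ``H`` models the blur of the optical system at one wavelength. All
kernels are odd-sided 2-D arrays normalized to unit mass, so convolving a
constant plane with ``H`` leaves it unchanged and the adjoint identity
``H_adj * 1 = 1`` holds in the deconvolution update algebra.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "PSFKernel",
    "gaussian_psf",
    "normalize_psf",
    "adjoint_psf",
    "load_psf",
    "apply_psf",
    "taper_edges",
]

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class PSFKernel:
    """A normalized 2-D point-spread function with odd side lengths."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] % 2 == 0 or v.shape[1] % 2 == 0:
            raise ValueError("PSF must be 2-D with odd height and width")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("PSF entries must be finite and >= 0")
        if abs(v.sum() - 1.0) > _NORM_TOL:
            raise ValueError("PSF must be normalized to unit sum")

    @property
    def radius(self) -> tuple[int, int]:
        """(row, column) half-widths of the kernel support."""
        return self.values.shape[0] // 2, self.values.shape[1] // 2

    @property
    def center(self) -> float:
        return float(self.values[self.radius])


def gaussian_psf(sigma: float, radius: int | None = None) -> PSFKernel:
    """Synthesize an isotropic Gaussian PSF with standard deviation ``sigma`` px.

    The support is truncated at ``radius`` (default ``ceil(4 sigma)``, which
    discards < 1e-4 of the mass before renormalization) and normalized to
    unit sum. The result is symmetric under 90-degree rotation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = math.ceil(4 * sigma)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    d = np.arange(-radius, radius + 1, dtype=np.float64)
    g1 = np.exp(-(d**2) / (2.0 * sigma**2))
    values = np.outer(g1, g1)
    return PSFKernel(values / values.sum())


def normalize_psf(raw: np.ndarray) -> PSFKernel:
    """Normalize a nonnegative array to a unit-mass odd-sided PSF kernel.

    Even-sided inputs are zero-padded by one trailing row/column so the center
    is unambiguous.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError("PSF must be 2-D")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise ValueError("PSF entries must be finite and >= 0")
    total = raw.sum()
    if total <= 0:
        raise ValueError("PSF must have at least one positive entry")
    pad_r = 1 - raw.shape[0] % 2
    pad_c = 1 - raw.shape[1] % 2
    if pad_r or pad_c:
        raw = np.pad(raw, ((0, pad_r), (0, pad_c)))
    return PSFKernel(raw / total)


def adjoint_psf(H: PSFKernel) -> PSFKernel:
    """The adjoint kernel ``H_{-s}``: H flipped about its center on both axes.

    Convolution with the adjoint is the transpose of convolution with ``H``;
    for symmetric kernels (e.g. Gaussian) the adjoint equals the original.
    """
    return PSFKernel(H.values[::-1, ::-1].copy())


def load_psf(path: str | os.PathLike) -> PSFKernel:
    """Load an empirical PSF from a TIFF/PNG image.

    The image minimum is subtracted as a flat background estimate before
    normalization; multi-channel PSF images are rejected (supply one file per
    wavelength).
    """
    from .io_formats import read_image

    stack = read_image(path)
    if stack.n_channels != 1:
        raise ValueError("a PSF image must be single-channel (one file per wavelength)")
    raw = stack.planes[0]
    return normalize_psf(raw - raw.min())


def apply_psf(
    plane: np.ndarray, H: PSFKernel, boundary: str = "reflect"
) -> np.ndarray:
    """Convolve a plane with the PSF under the given boundary rule.

    ``reflect`` mirrors the image at its borders (symmetric half-sample
    reflection); ``wrap`` is circular convolution. FFT-based; a unit-mass
    kernel maps a constant plane to itself under either rule.
    """
    plane = np.asarray(plane, dtype=np.float64)
    ry, rx = H.radius
    if boundary == "reflect":
        padded = np.pad(plane, ((ry, ry), (rx, rx)), mode="symmetric")
    elif boundary == "wrap":
        padded = np.pad(plane, ((ry, ry), (rx, rx)), mode="wrap")
    else:
        raise ValueError(f"unknown boundary rule {boundary!r}")
    out = fftconvolve(padded, H.values, mode="same")
    out = out[ry : ry + plane.shape[0], rx : rx + plane.shape[1]]
    return np.clip(out, 0.0, None)


def _edge_ramp(n: int, margin: int) -> np.ndarray:
    """1-D weight: 0 at the borders, rising smoothly to exactly 1 beyond `margin`."""
    idx = np.arange(n, dtype=np.float64)
    dist = np.minimum(idx, n - 1 - idx)
    t = np.minimum(dist / margin, 1.0)
    w = 0.5 - 0.5 * np.cos(np.pi * t)
    w[dist >= margin] = 1.0
    return w


def taper_edges(plane: np.ndarray, H: PSFKernel) -> np.ndarray:
    """Blend the image border toward its PSF-blurred version.

    FFT deconvolution treats the image as if it continued past its borders;
    intensity discontinuities there produce ringing. Within one PSF radius of
    each edge the image is blended with its blurred version using a cosine
    window that is 0 at the boundary and exactly 1 beyond the margin, so the
    interior is bit-identical to the input and a constant plane is unchanged.
    """
    plane = np.asarray(plane, dtype=np.float64)
    ry, rx = H.radius
    if plane.shape[0] <= 2 * ry + 1 or plane.shape[1] <= 2 * rx + 1:
        raise ValueError("plane must be larger than the PSF in both dimensions")
    blurred = apply_psf(plane, H, boundary="reflect")
    w = np.outer(_edge_ramp(plane.shape[0], ry), _edge_ramp(plane.shape[1], rx))
    return w * plane + (1.0 - w) * blurred
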