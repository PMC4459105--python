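"""Quantitative evaluation: SNR against ground truth, contrast, line profiles.

SNR here is the energy ratio in decibels,

    SNR = 10 log10( sum(truth^2) / sum((estimate - truth)^2) ),

computed per plane or pooled over all channels of a stack. Line profiles are
bilinear samples along a user-chosen segment, normalized by the trace
maximum ("intensity-normalized"), for comparing edge sharpness before and
after deconvolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ImageStack

__all__ = ["ProfileTrace", "snr_db", "stack_snr_db", "line_profile", "rms_contrast"]


@dataclass
class ProfileTrace:
    """Intensity-normalized samples along a line segment.

    positions: arc-length of each sample in pixels, strictly increasing.
    values: samples scaled so the trace maximum is 1 (all-zero traces stay 0).
    endpoints: the two (row, col) endpoints.
    channel: channel name, if sampled from a named stack.
    """

    positions: np.ndarray
    values: np.ndarray
    endpoints: tuple[tuple[float, float], tuple[float, float]]
    channel: str | None = None


def snr_db(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Signal-to-noise ratio of an estimate against the ground truth, in dB.

    Returns ``inf`` for an exact match. Invariant under simultaneous scaling
    of truth and error.
    """
    truth = np.asarray(truth, dtype=np.float64)
    estimate = np.asarray(estimate, dtype=np.float64)
    if truth.shape != estimate.shape:
        raise ValueError("truth and estimate must have the same shape")
    signal = float(np.sum(truth * truth))
    if signal == 0.0:
        raise ValueError("SNR is undefined for an all-zero reference")
    err = estimate - truth
    noise = float(np.sum(err * err))
    if noise == 0.0:
        return float("inf")
    return 10.0 * math.log10(signal / noise)


def stack_snr_db(truth: ImageStack, estimate: ImageStack) -> float:
    """SNR pooled over all channels: one energy ratio over the whole stack."""
    t = np.stack(truth.planes)
    e = np.stack(estimate.planes)
    return snr_db(t, e)


def line_profile(
    plane: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    n_samples: int = 100,
    channel: str | None = None,
) -> ProfileTrace:
    """Sample a plane along the segment p0 -> p1 (row, col coordinates).

    Uses bilinear interpolation at ``n_samples`` equally spaced points and
    normalizes by the trace maximum. Reversing the endpoints reverses the
    trace.
    """
    from scipy.ndimage import map_coordinates

    plane = np.asarray(plane, dtype=np.float64)
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    for r, c in (p0, p1):
        if not (0 <= r <= plane.shape[0] - 1 and 0 <= c <= plane.shape[1] - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    values = map_coordinates(plane, [rows, cols], order=1, mode="nearest")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    positions = t * length if length > 0 else np.arange(n_samples, dtype=float)
    peak = values.max()
    if peak > 0:
        values = values / peak
    return ProfileTrace(
        positions=positions,
        values=values,
        endpoints=(tuple(map(float, p0)), tuple(map(float, p1))),
        channel=channel,
    )


def rms_contrast(plane: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Coefficient of variation (std / mean) over a region; 0 if constant."""
    plane = np.asarray(plane, dtype=np.float64)
    if mask is not None:
        region = plane[np.asarray(mask, dtype=bool)]
    else:
        region = plane.ravel()
    if region.size == 0:
        raise ValueError("empty region")
    mean = float(region.mean())
    if mean == 0.0:
        return 0.0
    return float(region.std()) / mean
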