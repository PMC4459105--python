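"""Reading, writing and channel handling for multichannel microscopy images.

Images are held as an :class:`ImageStack`: an ordered list of 2-D float64
planes, one per fluorescence channel, on a working intensity scale of
``[0, 1]``. Integer files (8- or 16-bit TIFF/PNG) are rescaled by their dtype
maximum on read and quantized back on write, so a read/write round trip is
exact to within one quantization step per pixel.

Coordinate convention used throughout the package: row-major arrays, 0-based
indices, pixel centers at integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "read_image",
    "write_image",
    "split_channels",
    "merge_channels",
]

#: Channel labels assigned to multichannel files, in storage order.
#: Three-channel files follow the RGB storage convention of PNG/TIFF.
_DEFAULT_NAMES = {
    1: ["gray"],
    2: ["ch0", "ch1"],
    3: ["red", "green", "blue"],
    4: ["red", "green", "blue", "alpha"],
}

MAX_CHANNELS = 4


@dataclass
class ImageStack:
    """A multichannel 2-D image: one nonnegative float64 plane per channel."""

    planes: list[np.ndarray]
    channel_names: list[str] = field(default_factory=list)
    dtype_origin: int = 16  # bit depth of the file the stack came from

    def __post_init__(self) -> None:
        if not 1 <= len(self.planes) <= MAX_CHANNELS:
            raise ValueError(
                f"an ImageStack holds 1..{MAX_CHANNELS} planes, got {len(self.planes)}"
            )
        self.planes = [np.asarray(p, dtype=np.float64) for p in self.planes]
        shape = self.planes[0].shape
        for p in self.planes:
            if p.ndim != 2 or p.size == 0:
                raise ValueError("every plane must be a non-empty 2-D array")
            if p.shape != shape:
                raise ValueError("all planes must share the same height x width")
            if not np.all(np.isfinite(p)) or np.any(p < 0):
                raise ValueError("plane values must be finite and >= 0")
        if not self.channel_names:
            self.channel_names = list(_DEFAULT_NAMES[len(self.planes)])
        if len(self.channel_names) != len(self.planes):
            raise ValueError("one channel name per plane required")

    @property
    def n_channels(self) -> int:
        return len(self.planes)

    @property
    def height(self) -> int:
        return self.planes[0].shape[0]

    @property
    def width(self) -> int:
        return self.planes[0].shape[1]

    def plane(self, channel: int | str) -> np.ndarray:
        """Return the plane for a channel index or name."""
        if isinstance(channel, str):
            try:
                channel = self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"no channel {channel!r}; have {self.channel_names}"
                ) from None
        return self.planes[channel]


def _to_unit_scale(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Rescale an integer image array to [0, 1]; return (float plane, bit depth)."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max), info.bits
    # float input: assume already on the working scale
    return np.clip(arr.astype(np.float64), 0.0, None), 16


def read_image(path: str | os.PathLike) -> ImageStack:
    """Read a TIFF or PNG image (8/16-bit, grayscale or up to 4 channels).

    Integer pixel data are rescaled to ``[0, 1]`` by dividing by the dtype
    maximum; channel order is preserved as stored.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif ext == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {ext!r} (TIFF or PNG only)")

    arr = np.asarray(arr)
    if arr.ndim == 2:
        channels = [arr]
    elif arr.ndim == 3:
        # channels-last (H, W, C) vs multipage/channels-first (C, H, W)
        if arr.shape[2] <= MAX_CHANNELS:
            channels = [arr[:, :, c] for c in range(arr.shape[2])]
        elif arr.shape[0] <= MAX_CHANNELS:
            channels = [arr[c] for c in range(arr.shape[0])]
        else:
            raise ValueError(
                f"{path}: more than {MAX_CHANNELS} channels/pages not supported"
            )
    else:
        raise ValueError(f"{path}: expected a 2-D or 3-D image, got ndim={arr.ndim}")

    planes = []
    depth = 16
    for c in channels:
        plane, depth = _to_unit_scale(c)
        planes.append(plane)
    return ImageStack(planes=planes, dtype_origin=depth)


def write_image(stack: ImageStack, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a stack as TIFF or PNG at the requested bit depth.

    Values are clipped to ``[0, 1]``, scaled to the dtype maximum, and rounded
    half-up.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = os.fspath(path)
    maxv = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantized = [
        np.floor(np.clip(p, 0.0, 1.0) * maxv + 0.5).astype(dtype) for p in stack.planes
    ]
    arr = quantized[0] if len(quantized) == 1 else np.stack(quantized, axis=-1)

    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    elif ext == ".png":
        if bit_depth == 16 and arr.ndim == 3:
            raise ValueError(
                "16-bit multichannel PNG is not supported; use TIFF"
            )
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported image format: {ext!r} (TIFF or PNG only)")


def split_channels(stack: ImageStack) -> list[tuple[str, np.ndarray]]:
    """Return ``(channel_name, plane)`` pairs in storage order.

    Planes are copies: mutating one result does not alter the stack or the
    other results. Channels are deconvolved independently, each with its own
    PSF, so this is the natural unit of work.
    """
    return [(name, p.copy()) for name, p in zip(stack.channel_names, stack.planes)]


def merge_channels(
    channels: list[tuple[str, np.ndarray]], dtype_origin: int = 16
) -> ImageStack:
    """Inverse of :func:`split_channels`."""
    names = [name for name, _ in channels]
    planes = [p for _, p in channels]
    return ImageStack(planes=planes, channel_names=names, dtype_origin=dtype_origin)
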