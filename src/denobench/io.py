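"""Raster image I/O on the workbench's float 0-255 convention.

Reads PNG/TIFF/JPEG (8- or 16-bit, gray or RGB) into float64 arrays on
the 0-255 scale; writes clip and round to 8 bits.  Color images are
kept as an (H, W, 3) stack and dispatched per channel by the denoisers.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


class ImageIOError(IOError):
    pass


def read_image(path) -> np.ndarray:
    """Read an image as float64 on the 0-255 scale.

    Returns a 2-D array for grayscale input, (H, W, 3) for RGB (an alpha
    channel, if present, is dropped).  16-bit containers are rescaled by
    255/65535.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    elif arr.ndim == 3:
        arr = arr[:, :, 0]
    if raw.dtype == np.uint16:
        return arr.astype(float) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float)
    return arr.astype(float)


def to_uint8(plane: np.ndarray) -> np.ndarray:
    """Export quantization: clip to [0, 255] and round half to even."""
    return np.clip(np.rint(np.asarray(plane, dtype=float)), 0, 255).astype(np.uint8)


def write_image(plane: np.ndarray, path) -> None:
    """Write a float plane (or HxWx3 stack) as an 8-bit image."""
    path = Path(path)
    try:
        iio.imwrite(path, to_uint8(plane))
    except (OSError, ValueError) as exc:
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc


def split_channels(image: np.ndarray) -> list[np.ndarray]:
    if image.ndim == 2:
        return [image]
    return [image[:, :, c] for c in range(image.shape[2])]


def merge_channels(planes: list[np.ndarray]) -> np.ndarray:
    if len(planes) == 1:
        return planes[0]
    return np.stack(planes, axis=-1)


#: Rec. 601 luma weights, used by the luma-only color mode
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def apply_per_channel(fn, image: np.ndarray) -> np.ndarray:
    """Apply a plane->plane function to each channel independently."""
    return merge_channels([fn(plane) for plane in split_channels(image)])


def apply_luma(fn, image: np.ndarray) -> np.ndarray:
    """Denoise only the luma channel; chroma offsets pass through."""
    if image.ndim == 2:
        return fn(image)
    luma = image @ LUMA_WEIGHTS
    delta = fn(luma) - luma
    return image + delta[:, :, None]
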