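"""Gaussian pyramid construction and coarse-to-fine reconstruction.

A Gaussian pyramid represents an image at progressively coarser scales:
level 0 is the original plane, and each deeper level is obtained by
Gaussian smoothing followed by 2x decimation (``reduce``).  ``expand``
inverts the decimation by interpolating a coarse plane back onto the
finer grid.  ``reconstruct`` reassembles a full-resolution image from a
stack of per-level (possibly filtered) planes, substituting each level's
own low-pass content with the recursively reconstructed coarser
estimate, so that an unfiltered pyramid reassembles to the original
image exactly.

All arithmetic is float64 on the 0-255 intensity scale; quantization to
8 bits happens only at image export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DepthError(ValueError):
    """Requested pyramid depth is infeasible for the image size."""


class ShapeMismatchError(ValueError):
    """Plane shapes do not satisfy the operation's contract."""


@dataclass(frozen=True)
class SmoothingKernel:
    """Normalized 2-D Gaussian smoothing kernel.

    Attributes
    ----------
    taps : ndarray
        ``(size, size)`` array of non-negative weights summing to 1.
    sigma : float
        Standard deviation of the Gaussian, in pixels.
    size : int
        Odd side length of the kernel.
    """

    taps: np.ndarray
    sigma: float
    size: int


@dataclass
class GaussianPyramid:
    """Ordered stack of progressively reduced planes; index 0 is finest."""

    levels: list[np.ndarray]
    kernel: SmoothingKernel
    original_shapes: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.original_shapes:
            self.original_shapes = [lvl.shape for lvl in self.levels]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def make_kernel(sigma: float, size: int = 5) -> SmoothingKernel:
    """Build a normalized Gaussian kernel ``exp(-(x^2+y^2)/(2*sigma^2))``.

    Parameters
    ----------
    sigma : float
        Positive standard deviation controlling the level of blurring.
    size : int
        Odd side length, between 3 and 31.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if size % 2 == 0 or not 3 <= size <= 31:
        raise ValueError(f"size must be odd and in [3, 31], got {size}")
    half = size // 2
    coords = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(coords, coords)
    taps = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    taps /= taps.sum()
    return SmoothingKernel(taps=taps, sigma=float(sigma), size=int(size))


def _smooth(image: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # 'mirror' = reflect about the edge pixel without repeating it.
    return ndimage.convolve(np.asarray(image, dtype=float), taps, mode="mirror")


def reduce(image: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Blur with ``kernel`` and decimate by 2 (ceil halving of each axis)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 2:
        raise ShapeMismatchError(
            f"reduce needs a 2-D plane with min dimension >= 2, got shape {image.shape}"
        )
    return _smooth(image, kernel.taps)[::2, ::2]


def expand(
    image: np.ndarray, target_shape: tuple[int, int], kernel: SmoothingKernel
) -> np.ndarray:
    """Interpolate a coarse plane onto the finer ``target_shape`` grid.

    Known samples are placed at even grid positions, then the missing
    pixels are filled by normalized convolution with ``4 * kernel``
    (division by the convolved sample-occupancy mask), so constants are
    preserved exactly for any kernel and any odd/even target size.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    th, tw = target_shape
    if th not in (2 * h, 2 * h - 1) or tw not in (2 * w, 2 * w - 1):
        raise ShapeMismatchError(
            f"target shape {target_shape} incompatible with input shape {image.shape}"
        )
    stuffed = np.zeros((th, tw), dtype=float)
    mask = np.zeros((th, tw), dtype=float)
    stuffed[::2, ::2] = image
    mask[::2, ::2] = 1.0
    gained = 4.0 * kernel.taps
    num = ndimage.convolve(stuffed, gained, mode="mirror")
    den = ndimage.convolve(mask, gained, mode="mirror")
    return num / den


def max_depth(shape: tuple[int, int]) -> int:
    """Largest feasible pyramid depth: the coarsest level keeps min dim >= 2."""
    depth = 1
    h, w = shape
    while min(-(-h // 2), -(-w // 2)) >= 2:
        h, w = -(-h // 2), -(-w // 2)
        depth += 1
    return depth


def build_pyramid(
    image: np.ndarray, n_levels: int, kernel: SmoothingKernel | None = None
) -> GaussianPyramid:
    """Build an ``n_levels``-deep Gaussian pyramid of ``image``."""
    image = np.asarray(image, dtype=float)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if kernel is None:
        kernel = make_kernel(1.0, 5)
    feasible = max_depth(image.shape)
    if n_levels > feasible:
        raise DepthError(
            f"n_levels={n_levels} too deep for shape {image.shape}; "
            f"max feasible depth is {feasible}"
        )
    levels = [image]
    for _ in range(n_levels - 1):
        levels.append(reduce(levels[-1], kernel))
    return GaussianPyramid(levels=levels, kernel=kernel)


def reconstruct(
    denoised_levels: list[np.ndarray], pyramid: GaussianPyramid
) -> np.ndarray:
    """Coarse-to-fine reassembly of per-level planes into one image.

    At each level the plane's own low-pass content
    ``expand(reduce(plane))`` is replaced by the expanded reconstruction
    of the coarser levels:

        r_coarsest = plane_coarsest
        r_l = plane_l - expand(reduce(plane_l)) + expand(r_{l+1})

    Because ``reduce(levels[l]) == levels[l+1]`` for an unfiltered
    pyramid, feeding the pyramid's own levels back in returns the
    original image exactly (telescoping identity).
    """
    if len(denoised_levels) != pyramid.n_levels:
        raise ShapeMismatchError(
            f"got {len(denoised_levels)} planes for a {pyramid.n_levels}-level pyramid"
        )
    for plane, ref in zip(denoised_levels, pyramid.levels):
        if plane.shape != ref.shape:
            raise ShapeMismatchError(
                f"plane shape {plane.shape} does not match pyramid level {ref.shape}"
            )
    kernel = pyramid.kernel
    result = np.asarray(denoised_levels[-1], dtype=float)
    for l in range(pyramid.n_levels - 2, -1, -1):
        plane = np.asarray(denoised_levels[l], dtype=float)
        lowpass = expand(reduce(plane, kernel), plane.shape, kernel)
        result = plane - lowpass + expand(result, plane.shape, kernel)
    return result
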