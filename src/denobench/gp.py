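"""Multiscale Gaussian-pyramid denoiser with level-specific filters.

The method builds a Gaussian pyramid of the noisy image and applies a
different spatial filter at each scale: an edge-preserving bilateral
filter at the finest level (where edges and texture live), a median
filter at intermediate levels (where decimation has clustered impulsive
noise), and mild Gaussian smoothing at the coarsest levels (broad,
spatially homogeneous intensity variation).  The filtered levels are
then reassembled coarse-to-fine by :func:`denobench.pyramid.reconstruct`.

The default five-level plan is bilateral(diameter 5, intensity sigma 7)
at level 0, 3x3 median at levels 1-2, and Gaussian(sigma 0.7, 5x5) at
levels 3-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .pyramid import (
    GaussianPyramid,
    SmoothingKernel,
    build_pyramid,
    make_kernel,
    reconstruct,
)


@dataclass(frozen=True)
class Bilateral:
    """Range-and-space weighted average over a square window."""

    diameter: int = 5
    sigma_intensity: float = 7.0
    sigma_spatial: float = 2.5


@dataclass(frozen=True)
class Median:
    kernel_size: int = 3


@dataclass(frozen=True)
class Gaussian:
    sigma: float = 0.7
    kernel_size: int = 5


@dataclass(frozen=True)
class Identity:
    pass


FilterSpec = Bilateral | Median | Gaussian | Identity


@dataclass(frozen=True)
class LevelFilterPlan:
    """One filter assignment per pyramid level, finest first."""

    assignments: tuple[FilterSpec, ...]

    def __post_init__(self) -> None:
        for spec in self.assignments:
            if isinstance(spec, Bilateral):
                _check_odd(spec.diameter, "diameter")
                _check_positive(spec.sigma_intensity, "sigma_intensity")
                _check_positive(spec.sigma_spatial, "sigma_spatial")
            elif isinstance(spec, Median):
                _check_odd(spec.kernel_size, "kernel_size")
            elif isinstance(spec, Gaussian):
                _check_odd(spec.kernel_size, "kernel_size")
                _check_positive(spec.sigma, "sigma")

    def __len__(self) -> int:
        return len(self.assignments)


def _check_odd(value: int, name: str) -> None:
    if value % 2 == 0 or value < 3:
        raise ValueError(f"{name} must be odd and >= 3, got {value}")


def _check_positive(value: float, name: str) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")


def default_plan(n_levels: int) -> LevelFilterPlan:
    """Level->filter assignment: bilateral finest, median middle, Gaussian coarsest.

    For five levels this is the reference configuration
    ``[bilateral, median, median, gaussian, gaussian]``; other depths
    band proportionally (roughly a third of the levels per filter, at
    least one bilateral level).
    """
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    n_bilateral = max(1, n_levels // 3)
    remainder = n_levels - n_bilateral
    n_median = remainder // 2
    n_gaussian = remainder - n_median
    assignments = (
        (Bilateral(),) * n_bilateral + (Median(),) * n_median + (Gaussian(),) * n_gaussian
    )
    return LevelFilterPlan(assignments=assignments)


def bilateral_filter(
    image: np.ndarray,
    diameter: int = 5,
    sigma_intensity: float = 7.0,
    sigma_spatial: float = 2.5,
) -> np.ndarray:
    """Edge-preserving bilateral filter.

    Each pixel becomes the average of its ``diameter x diameter``
    neighborhood weighted by both spatial distance (Gaussian with
    ``sigma_spatial``) and intensity difference to the center pixel
    (Gaussian with ``sigma_intensity`` on the 0-255 scale).  Constant
    images are preserved exactly.
    """
    _check_odd(diameter, "diameter")
    _check_positive(sigma_intensity, "sigma_intensity")
    _check_positive(sigma_spatial, "sigma_spatial")
    image = np.asarray(image, dtype=float)
    radius = diameter // 2
    padded = np.pad(image, radius, mode="reflect")
    h, w = image.shape
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    inv2ss = 1.0 / (2.0 * sigma_spatial**2)
    inv2si = 1.0 / (2.0 * sigma_intensity**2)
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            shifted = padded[radius + di : radius + di + h, radius + dj : radius + dj + w]
            weight = np.exp(
                -(di * di + dj * dj) * inv2ss - (shifted - image) ** 2 * inv2si
            )
            num += weight * shifted
            den += weight
    return num / den


def median_filter(image: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Per-pixel window median with reflective borders."""
    _check_odd(kernel_size, "kernel_size")
    return ndimage.median_filter(
        np.asarray(image, dtype=float), size=kernel_size, mode="mirror"
    )


def gaussian_filter(
    image: np.ndarray, sigma: float = 0.7, kernel_size: int = 5
) -> np.ndarray:
    """Convolution with a normalized Gaussian kernel, reflective borders."""
    kernel = make_kernel(sigma, kernel_size)
    return ndimage.convolve(
        np.asarray(image, dtype=float), kernel.taps, mode="mirror"
    )


def apply_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    if isinstance(spec, Bilateral):
        return bilateral_filter(
            image, spec.diameter, spec.sigma_intensity, spec.sigma_spatial
        )
    if isinstance(spec, Median):
        return median_filter(image, spec.kernel_size)
    if isinstance(spec, Gaussian):
        return gaussian_filter(image, spec.sigma, spec.kernel_size)
    if isinstance(spec, Identity):
        return np.asarray(image, dtype=float)
    raise ValueError(f"unknown filter spec {spec!r}")


def denoise_gp(
    image: np.ndarray,
    n_levels: int = 5,
    plan: LevelFilterPlan | None = None,
    kernel: SmoothingKernel | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Denoise one plane with the multiscale pyramid method.

    Returns the reconstructed image (float, 0-255 scale, unclipped) and
    the per-level filtered planes for inspection.
    """
    if plan is None:
        plan = default_plan(n_levels)
    if len(plan) != n_levels:
        raise ValueError(
            f"plan has {len(plan)} entries for a {n_levels}-level pyramid"
        )
    pyramid = build_pyramid(image, n_levels, kernel)
    denoised = [
        apply_filter(level, spec)
        for level, spec in zip(pyramid.levels, plan.assignments)
    ]
    return reconstruct(denoised, pyramid), denoised
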