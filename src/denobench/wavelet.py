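"""Wavelet-shrinkage denoising baselines.

Multi-level separable 2-D discrete wavelet transform (orthogonal
families Haar, db4, coif4, sym4), soft or hard thresholding of the
detail subbands (LH/HL/HH), and inverse transform.  The approximation
subband is never thresholded.

The default threshold is the universal (VisuShrink) choice
``T = sigma_hat * sqrt(2 ln N)`` with the noise scale estimated robustly
from the finest diagonal subband, ``sigma_hat = median(|HH1|)/0.6745``.
The transforms themselves are delegated to PyWavelets with symmetric
signal extension; recorded original shapes make the round trip exact
for odd sizes too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .pyramid import DepthError, ShapeMismatchError

FAMILIES = ("haar", "db4", "coif4", "sym4")

#: scipy.stats.norm.ppf(0.75) — scales the MAD of a Gaussian to its SD
_MAD_TO_SIGMA = 0.6744897501960817


@dataclass
class SubbandTree:
    """Wavelet coefficient stack: coarsest LL plus per-level details.

    ``details`` is ordered coarsest-first (matching PyWavelets); each
    entry is the (LH, HL, HH) triple for that level, where LH/HL/HH are
    the vertical/horizontal/diagonal detail planes.
    """

    approx: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    family: str
    original_shape: tuple[int, int]

    @property
    def n_levels(self) -> int:
        return len(self.details)

    @property
    def finest_diagonal(self) -> np.ndarray:
        """HH subband at the finest decomposition level."""
        return self.details[-1][2]


@dataclass(frozen=True)
class ThresholdRule:
    """Shrinkage rule: soft/hard mode and threshold selector.

    ``value=None`` selects the universal threshold; a fixed non-negative
    ``value`` uses that T directly.  ``scope`` controls whether the
    universal T is computed once from the whole-image coefficient count
    ("global") or per decomposition level ("per-level").
    """

    mode: str = "soft"
    value: float | None = None
    scope: str = "per-level"

    def __post_init__(self) -> None:
        if self.mode not in ("soft", "hard"):
            raise ValueError(f"mode must be 'soft' or 'hard', got {self.mode!r}")
        if self.value is not None and self.value < 0:
            raise ValueError(f"fixed threshold must be >= 0, got {self.value}")
        if self.scope not in ("global", "per-level"):
            raise ValueError(f"scope must be 'global' or 'per-level', got {self.scope!r}")


def _wavelet(family: str) -> pywt.Wavelet:
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    return pywt.Wavelet(family)


def decompose(image: np.ndarray, family: str = "db4", n_levels: int = 2) -> SubbandTree:
    """Recursive separable 2-D wavelet decomposition of one plane."""
    image = np.asarray(image, dtype=float)
    wav = _wavelet(family)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    # feasible as long as every approximation stage keeps min dimension
    # >= 2 (symmetric extension makes the round trip exact regardless of
    # the usual max-level heuristic)
    h, w = image.shape
    feasible = 0
    while min(h, w) >= 2 and feasible < n_levels:
        h = pywt.dwt_coeff_len(h, wav.dec_len, mode="symmetric")
        w = pywt.dwt_coeff_len(w, wav.dec_len, mode="symmetric")
        feasible += 1
    if n_levels > feasible:
        raise DepthError(
            f"n_levels={n_levels} infeasible for shape {image.shape} with "
            f"{family} (max {feasible})"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pywt warns past its depth heuristic
        coeffs = pywt.wavedec2(image, wav, mode="symmetric", level=n_levels)
    approx = coeffs[0]
    # pywt orders each detail tuple (cH, cV, cD) = (horizontal, vertical,
    # diagonal); store as (LH, HL, HH) = (vertical detail, horizontal
    # detail, diagonal detail) following the subband naming convention.
    details = [(cv, ch, cd) for (ch, cv, cd) in coeffs[1:]]
    return SubbandTree(
        approx=approx, details=details, family=family, original_shape=image.shape
    )


def soft_threshold(coeffs: np.ndarray, t: float) -> np.ndarray:
    """sign(w) * max(|w| - T, 0): shrinks magnitudes by T, zeroes small ones."""
    return np.sign(coeffs) * np.maximum(np.abs(coeffs) - t, 0.0)


def hard_threshold(coeffs: np.ndarray, t: float) -> np.ndarray:
    """Keep w where |w| >= T, zero otherwise."""
    return np.where(np.abs(coeffs) >= t, coeffs, 0.0)


def estimate_noise_sigma(finest_diagonal: np.ndarray) -> float:
    """Robust noise-scale estimate: median(|HH1|) / 0.6745."""
    return float(np.median(np.abs(finest_diagonal)) / _MAD_TO_SIGMA)


def universal_threshold(sigma: float, n_coefficients: int) -> float:
    """VisuShrink threshold T = sigma * sqrt(2 ln N)."""
    if n_coefficients < 2:
        raise ValueError("universal threshold needs at least 2 coefficients")
    return float(sigma * np.sqrt(2.0 * np.log(n_coefficients)))


def threshold_coefficients(tree: SubbandTree, rule: ThresholdRule) -> SubbandTree:
    """Apply the shrinkage rule to every detail subband; LL is untouched."""
    shrink = soft_threshold if rule.mode == "soft" else hard_threshold
    if rule.value is not None:
        thresholds = [rule.value] * tree.n_levels
    else:
        sigma = estimate_noise_sigma(tree.finest_diagonal)
        if rule.scope == "global":
            n = int(np.prod(tree.original_shape))
            thresholds = [universal_threshold(sigma, n)] * tree.n_levels
        else:
            thresholds = [
                universal_threshold(sigma, sum(band.size for band in level))
                for level in tree.details
            ]
    new_details = [
        tuple(shrink(band, t) for band in level)
        for level, t in zip(tree.details, thresholds)
    ]
    return SubbandTree(
        approx=tree.approx.copy(),
        details=new_details,
        family=tree.family,
        original_shape=tree.original_shape,
    )


def reconstruct_wavelet(tree: SubbandTree) -> np.ndarray:
    """Inverse separable transform back to one plane of the original shape."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expected = pywt.wavedec2(
            np.zeros(tree.original_shape), _wavelet(tree.family),
            mode="symmetric", level=tree.n_levels,
        )
    if tree.approx.shape != expected[0].shape:
        raise ShapeMismatchError(
            f"approximation shape {tree.approx.shape} inconsistent with "
            f"original shape {tree.original_shape}"
        )
    coeffs = [tree.approx]
    for (lh, hl, hh), (eh, ev, _ed) in zip(tree.details, expected[1:]):
        if lh.shape != ev.shape or hl.shape != eh.shape or hh.shape != ev.shape:
            raise ShapeMismatchError("corrupted detail subband shapes")
        coeffs.append((hl, lh, hh))  # back to pywt (cH, cV, cD) order
    out = pywt.waverec2(coeffs, _wavelet(tree.family), mode="symmetric")
    h, w = tree.original_shape
    return out[:h, :w]


def denoise_wavelet(
    image: np.ndarray,
    family: str = "db4",
    n_levels: int = 2,
    rule: ThresholdRule | None = None,
) -> np.ndarray:
    """Decompose, threshold the detail coefficients, and invert."""
    if rule is None:
        rule = ThresholdRule()
    tree = decompose(image, family, n_levels)
    return reconstruct_wavelet(threshold_coefficients(tree, rule))
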