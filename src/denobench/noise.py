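"""Synthetic clean phantoms and seeded noise generation.

Provides deterministic test imagery (piecewise-smooth phantoms with
sharp edges) and the noise families commonly encountered in natural and
medical imagery: additive Gaussian, lognormal, uniform, exponential,
Rayleigh and Erlang noise (all location-shifted to mean zero so the
additive decomposition noisy = clean + noise holds), signal-dependent
Poisson shot noise, multiplicative speckle, salt-and-pepper impulses,
and a composite camera model (fixed-pattern gain, shot, read and
impulse noise).

Default severities are chosen so the noisy input lands in the
18-28 dB PSNR band on the bundled phantoms (additive families have
noise SD ~= 15 on the 0-255 scale); see docs/methods.md.  Outputs are
float and unclipped — clipping to [0, 255] happens only at 8-bit
export.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FAMILIES = (
    "gaussian",
    "lognormal",
    "uniform",
    "exponential",
    "poisson",
    "salt_pepper",
    "rayleigh",
    "speckle",
    "erlang",
    "camera_mix",
)

PHANTOM_KINDS = ("shepp_like", "geometric_shapes", "gradient_texture", "edge_grid")

#: per-family default parameters (additive families: noise SD ~= 15)
DEFAULT_PARAMS: dict[str, dict] = {
    "gaussian": {"sigma": 15.0},
    "lognormal": {"sigma_log": 0.5, "scale": 25.0},
    "uniform": {"half_width": 26.0},
    "exponential": {"scale": 15.0},
    "poisson": {"gain": 0.5},
    "salt_pepper": {"density": 0.05},
    "rayleigh": {"scale": 23.0},
    "speckle": {"sigma": 0.12},
    "erlang": {"shape": 2, "scale": 10.6},
    "camera_mix": {
        "shot_gain": 0.5,
        "read_sigma": 5.0,
        "fpn_sigma": 0.02,
        "impulse_density": 0.002,
    },
}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise family, parameters and seed; identical spec => identical output."""

    family: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        merged = {**DEFAULT_PARAMS[self.family], **self.params}
        if not 0.0 <= merged.get("density", 0.0) <= 1.0:
            raise ValueError("density must be in [0, 1]")
        for key in ("sigma", "scale", "half_width", "gain", "sigma_log"):
            if key in merged and merged[key] <= 0:
                raise ValueError(f"{key} must be positive")
        object.__setattr__(self, "params", merged)


@dataclass(frozen=True)
class PhantomSpec:
    kind: str = "shepp_like"
    size: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if min(self.size) < 32:
            raise ValueError(f"phantom size must be >= 32x32, got {self.size}")


def _grid(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = size
    yy = np.linspace(-1.0, 1.0, h)[:, None]
    xx = np.linspace(-1.0, 1.0, w)[None, :]
    return yy, xx


def _shepp_like(size: tuple[int, int]) -> np.ndarray:
    # piecewise-constant ellipse phantom: head outline, interior, two
    # "ventricles", and two small bright lesions -> >= 4 intensity plateaus
    yy, xx = _grid(size)
    img = np.zeros(size, dtype=float)
    ellipses = [
        # (cx, cy, a, b, value set inside)
        (0.0, 0.0, 0.90, 0.85, 60.0),
        (0.0, 0.05, 0.78, 0.72, 140.0),
        (-0.25, 0.0, 0.18, 0.35, 90.0),
        (0.25, 0.0, 0.18, 0.35, 90.0),
        (0.0, -0.45, 0.12, 0.12, 220.0),
        (0.0, 0.45, 0.08, 0.08, 200.0),
    ]
    for cx, cy, a, b, value in ellipses:
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img[inside] = value
    return img


def _geometric_shapes(size: tuple[int, int]) -> np.ndarray:
    yy, xx = _grid(size)
    img = np.full(size, 40.0)
    img[(xx > -0.8) & (xx < -0.2) & (yy > -0.8) & (yy < -0.1)] = 180.0
    img[(xx - 0.4) ** 2 + (yy + 0.4) ** 2 < 0.09] = 230.0
    img[(xx > 0.1) & (yy > 0.2) & (xx + yy < 1.1)] = 120.0
    img[(xx > -0.9) & (xx < 0.9) & (yy > 0.75) & (yy < 0.9)] = 80.0
    return img


def _gradient_texture(size: tuple[int, int], seed: int) -> np.ndarray:
    yy, xx = _grid(size)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * math.pi, size=2)
    img = 100.0 + 80.0 * xx + 30.0 * np.sin(8 * math.pi * xx + phase[0]) * np.sin(
        6 * math.pi * yy + phase[1]
    )
    img += 40.0 * np.exp(-((xx - 0.3) ** 2 + (yy + 0.2) ** 2) / 0.05)
    return np.clip(img, 0.0, 255.0)


def _edge_grid(size: tuple[int, int]) -> np.ndarray:
    h, w = size
    img = np.full(size, 64.0)
    img[::16, :] = 200.0
    img[:, ::16] = 200.0
    rr = np.arange(h)[:, None] + np.arange(w)[None, :]
    img[rr % 32 == 0] = 150.0
    return img


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic clean plane with smooth regions and sharp edges."""
    if spec.kind == "shepp_like":
        return _shepp_like(spec.size)
    if spec.kind == "geometric_shapes":
        return _geometric_shapes(spec.size)
    if spec.kind == "gradient_texture":
        return _gradient_texture(spec.size, spec.seed)
    return _edge_grid(spec.size)


def add_noise(image: np.ndarray, spec: NoiseSpec, centered: bool = True) -> np.ndarray:
    """Corrupt ``image`` according to ``spec``; float output, unclipped.

    Additive non-Gaussian families are location-shifted so the added
    noise has mean zero (pass ``centered=False`` for the raw draws).
    """
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    shape = image.shape
    fam = spec.family
    if fam == "gaussian":
        return image + rng.normal(0.0, p["sigma"], shape)
    if fam == "lognormal":
        draws = p["scale"] * rng.lognormal(0.0, p["sigma_log"], shape)
        if centered:
            draws -= p["scale"] * math.exp(p["sigma_log"] ** 2 / 2.0)
        return image + draws
    if fam == "uniform":
        return image + rng.uniform(-p["half_width"], p["half_width"], shape)
    if fam == "exponential":
        draws = rng.exponential(p["scale"], shape)
        if centered:
            draws -= p["scale"]
        return image + draws
    if fam == "rayleigh":
        draws = rng.rayleigh(p["scale"], shape)
        if centered:
            draws -= p["scale"] * math.sqrt(math.pi / 2.0)
        return image + draws
    if fam == "erlang":
        draws = rng.gamma(p["shape"], p["scale"], shape)
        if centered:
            draws -= p["shape"] * p["scale"]
        return image + draws
    if fam == "poisson":
        gain = p["gain"]
        return rng.poisson(np.clip(image, 0.0, None) * gain).astype(float) / gain
    if fam == "speckle":
        return image * (1.0 + rng.normal(0.0, p["sigma"], shape))
    if fam == "salt_pepper":
        corrupt = rng.random(shape) < p["density"]
        salt = rng.random(shape) < 0.5
        noisy = image.copy()
        noisy[corrupt & salt] = 255.0
        noisy[corrupt & ~salt] = 0.0
        return noisy
    if fam == "camera_mix":
        return camera_mix(
            image,
            shot_gain=p["shot_gain"],
            read_sigma=p["read_sigma"],
            fpn_sigma=p["fpn_sigma"],
            impulse_density=p["impulse_density"],
            seed=spec.seed,
        )
    raise ValueError(f"unknown noise family {fam!r}")


def camera_mix(
    image: np.ndarray,
    shot_gain: float = 0.5,
    read_sigma: float = 5.0,
    fpn_sigma: float = 0.02,
    impulse_density: float = 0.002,
    seed: int = 0,
) -> np.ndarray:
    """Composite sensor noise: fixed-pattern gain, shot, read, impulses.

    A static per-pixel multiplicative gain field (drawn once per seed)
    models fixed-pattern non-uniformity; Poisson shot noise is
    signal-dependent (variance proportional to intensity); additive
    Gaussian read noise and a sparse impulse layer complete the model.
    All parameters zero gives the identity.
    """
    for name, value in (
        ("shot_gain", shot_gain),
        ("read_sigma", read_sigma),
        ("fpn_sigma", fpn_sigma),
        ("impulse_density", impulse_density),
    ):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    image = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    out = image.copy()
    if fpn_sigma > 0:
        out = out * (1.0 + rng.normal(0.0, fpn_sigma, image.shape))
    if shot_gain > 0:
        out = rng.poisson(np.clip(out, 0.0, None) * shot_gain).astype(float) / shot_gain
    if read_sigma > 0:
        out = out + rng.normal(0.0, read_sigma, image.shape)
    if impulse_density > 0:
        corrupt = rng.random(image.shape) < impulse_density
        salt = rng.random(image.shape) < 0.5
        out[corrupt & salt] = 255.0
        out[corrupt & ~salt] = 0.0
    return out


def make_benchmark_set(
    out_dir,
    n_images: int = 10,
    phantom_kinds: tuple[str, ...] = PHANTOM_KINDS,
    noise_families: tuple[str, ...] = ("gaussian",),
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> pd.DataFrame:
    """Write paired clean/noisy PNGs plus a manifest CSV; reproducible.

    Generates ``n_images`` clean phantoms (cycling through
    ``phantom_kinds``) and one noisy version per (image, family) pair.
    Returns the manifest frame (columns path_clean, path_noisy, family,
    params, seed).
    """
    from .io import write_image

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_images):
        kind = phantom_kinds[i % len(phantom_kinds)]
        phantom_seed = (seed * 1_000_003 + 7919 * i) % 2**31
        clean = make_phantom(PhantomSpec(kind=kind, size=size, seed=phantom_seed))
        clean_path = out_dir / f"clean_{i:03d}_{kind}.png"
        write_image(clean, clean_path)
        for j, family in enumerate(noise_families):
            pair_seed = (seed * 1_000_003 + 7919 * i + 104_729 * (j + 1)) % 2**31
            spec = NoiseSpec(family=family, seed=pair_seed)
            noisy = add_noise(clean, spec)
            noisy_path = out_dir / f"noisy_{i:03d}_{family}.png"
            write_image(noisy, noisy_path)
            rows.append(
                {
                    "path_clean": str(clean_path),
                    "path_noisy": str(noisy_path),
                    "family": family,
                    "params": json.dumps(spec.params, sort_keys=True),
                    "seed": pair_seed,
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["path_clean", "path_noisy", "family", "params", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
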