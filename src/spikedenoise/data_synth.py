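"""Degradation models and synthetic grayscale image generation.

Noise levels follow the common convention of quoting sigma on the 0-255
intensity scale while images live in [0, 1]: a noise level of 25 means
additive Gaussian noise with standard deviation 25/255.  Noisy images are
not clipped by default, so the expected PSNR of an AWGN-degraded image is
exactly ``20 log10(255 / sigma)`` (20.17 dB at sigma 25, 14.15 dB at 50).

The synthetic generator produces smooth gradients, checkerboards, blob
scenes and band-limited textures in [0.1, 0.9] -- headroom so that additive
noise rarely leaves the displayable range.  It stands in for natural-image
training corpora so that the full pipeline runs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

__all__ = [
    "NoiseSpec",
    "add_gaussian",
    "add_speckle",
    "add_noise",
    "make_synthetic_images",
    "extract_patches",
]


@dataclass
class NoiseSpec:
    """Degradation model: ``gaussian`` (y = x + v) or ``speckle``
    (y = x + x*v), with sigma on the 0-255 scale and a reproducibility
    seed."""

    model: str = "gaussian"
    sigma: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "speckle"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def add_gaussian(x, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Additive white Gaussian degradation ``y = x + v``,
    v ~ N(0, (sigma/255)^2) i.i.d. per pixel."""
    if spec.model != "gaussian":
        raise ValueError("spec.model must be 'gaussian'")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(spec.seed)
    y = x + rng.normal(0.0, spec.sigma / 255.0, size=x.shape)
    return np.clip(y, 0.0, 1.0) if clip else y


def add_speckle(x, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Multiplicative speckle degradation ``y = x + x * v``,
    v ~ N(0, (sigma/255)^2); the error variance at a pixel is
    ``x^2 (sigma/255)^2``, as in ultrasound / OCT imagery."""
    if spec.model != "speckle":
        raise ValueError("spec.model must be 'speckle'")
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(spec.seed)
    y = x + x * rng.normal(0.0, spec.sigma / 255.0, size=x.shape)
    return np.clip(y, 0.0, 1.0) if clip else y


def add_noise(x, spec: NoiseSpec, clip: bool = False) -> np.ndarray:
    """Dispatch on ``spec.model``."""
    if spec.model == "gaussian":
        return add_gaussian(x, spec, clip)
    return add_speckle(x, spec, clip)


def _one_image(kind: str, size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / max(size - 1, 1)
    if kind == "gradient":
        angle = rng.uniform(0, 2 * np.pi)
        img = np.cos(angle) * xx + np.sin(angle) * yy
    elif kind == "checker":
        cell = max(2, size // int(rng.integers(4, 9)))
        img = ((np.arange(size)[:, None] // cell + np.arange(size)[None, :] // cell) % 2).astype(float)
        img = gaussian_filter(img, sigma=1.0)
    elif kind == "blobs":
        img = np.full((size, size), 0.25)
        for _ in range(int(rng.integers(4, 9))):
            cy, cx = rng.uniform(0, size, 2)
            r = rng.uniform(size / 12, size / 4)
            level = rng.uniform(0.0, 1.0)
            mask = (np.arange(size)[:, None] - cy) ** 2 + (np.arange(size)[None, :] - cx) ** 2 <= r**2
            img = np.where(mask, level, img)
        img = gaussian_filter(img, sigma=size / 64 + 0.5)
    elif kind == "texture":
        img = gaussian_filter(rng.normal(size=(size, size)), sigma=size / 32 + 1.0)
    else:
        raise ValueError(f"unknown image kind {kind!r}")
    lo, hi = img.min(), img.max()
    if hi - lo < 1e-12:
        return np.full((size, size), 0.5)
    return 0.1 + 0.8 * (img - lo) / (hi - lo)


def make_synthetic_images(kind: str = "blobs", size: int = 64, count: int = 1,
                          seed: int = 0) -> list:
    """Deterministic set of synthetic grayscale images in [0.1, 0.9].

    Kinds: ``gradient`` (oriented linear ramp), ``checker`` (softened
    checkerboard), ``blobs`` (piecewise-constant disks, smoothed),
    ``texture`` (band-limited Gaussian random field), ``mixed`` (cycles
    through all four).
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    kinds = ["gradient", "checker", "blobs", "texture"] if kind == "mixed" else [kind]
    return [_one_image(kinds[i % len(kinds)], size, rng) for i in range(count)]


def extract_patches(images, patch: int = 40, stride: int = None) -> list:
    """Row-major, top-left-anchored tiling of each image into
    ``patch x patch`` windows with the given stride (default: patch)."""
    stride = patch if stride is None else stride
    out = []
    for img in images:
        img = np.asarray(img, dtype=float)
        if img.shape[0] < patch or img.shape[1] < patch:
            raise ValueError(
                f"patch {patch} exceeds image size {img.shape}"
            )
        win = sliding_window_view(img, (patch, patch))[::stride, ::stride]
        out.extend(win.reshape(-1, patch, patch))
    return out
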