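"""Grayscale conversion and edge-preserving bilateral denoising.

The measurement pipeline applies exactly two preprocessing steps to a
radiograph before detection: conversion to a single luminance channel
and a bilateral filter, which smooths background noise while keeping
the high-contrast bone/implant edges that the Hough stage depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FilterParams", "to_grayscale", "bilateral_denoise"]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class FilterParams:
    """Bilateral filter parameters.

    diameter
        Side length in pixels of the square filter neighbourhood
        (odd, >= 3).
    sigma_color
        Range kernel width in intensity units (0-255 scale); intensity
        differences much larger than this are treated as edges and not
        averaged across.
    sigma_space
        Spatial kernel width in pixels.
    """

    diameter: int = 9
    sigma_color: float = 50.0
    sigma_space: float = 5.0

    def __post_init__(self):
        if self.diameter < 3 or self.diameter % 2 == 0:
            raise ValueError("diameter must be odd and >= 3")
        if self.sigma_color <= 0 or self.sigma_space <= 0:
            raise ValueError("sigmas must be positive")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an image to a single luminance channel.

    Already-grayscale (2-D) input is returned unchanged; 3-channel
    input is combined with the 0.299/0.587/0.114 luminance weights
    (rounded back to the input dtype for integer input).
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 3:
        gray = image.astype(np.float64) @ _LUMA
        if np.issubdtype(image.dtype, np.integer):
            return np.round(gray).astype(image.dtype)
        return gray
    raise ValueError(f"expected a 2-D or 3-channel image, got shape {image.shape}")


def bilateral_denoise(image: np.ndarray, params: FilterParams | None = None) -> np.ndarray:
    """Edge-preserving bilateral filter.

    Each output pixel is a weighted mean of its ``diameter x diameter``
    neighbourhood (reflect-padded at the borders), with weights the
    product of a spatial Gaussian and an intensity-difference Gaussian.
    Being a convex combination of input pixels, the output range never
    leaves ``[min(input), max(input)]``.
    """
    params = params or FilterParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("bilateral_denoise expects a grayscale (2-D) image")
    img = image.astype(np.float64)
    r = params.diameter // 2
    padded = np.pad(img, r, mode="reflect")
    h, w = img.shape
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv2_sc = 1.0 / (2.0 * params.sigma_color**2)
    inv2_ss = 1.0 / (2.0 * params.sigma_space**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = np.exp(
                -(dx * dx + dy * dy) * inv2_ss - (shifted - img) ** 2 * inv2_sc
            )
            num += wgt * shifted
            den += wgt
    return num / den
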