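"""Truncated Gaussian window defining the local neighbourhoods O_y.

Every local statistic in this package is a weighted average over a circular
neighbourhood O_y = {x : |x - y| <= r}, weighted by a Gaussian of width
``sigma`` that is truncated to zero outside the circle and normalised to sum
to one.  The window is realised as a (2r+1) x (2r+1) mask; cells of the
square mask whose Euclidean distance from the centre exceeds ``r`` are
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["KernelMask", "build_truncated_gaussian_kernel", "local_weighted_convolve"]


@dataclass(frozen=True)
class KernelMask:
    """Normalised, circularly truncated Gaussian weighting window.

    Attributes
    ----------
    weights : ndarray
        (2r+1, 2r+1) nonnegative array summing to 1; zero where the
        Euclidean distance from the centre exceeds ``radius``.
    radius : int
        Truncation radius r in pixels.
    sigma : float
        Standard deviation of the Gaussian, in pixels.
    normalizer : float
        The constant a such that weights = exp(-d^2 / 2 sigma^2) / a inside
        the circle.
    """

    weights: np.ndarray = field(repr=False)
    radius: int
    sigma: float
    normalizer: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def build_truncated_gaussian_kernel(sigma: float, radius: int) -> KernelMask:
    """Build the circularly truncated Gaussian window omega.

    Weights are ``exp(-d^2 / (2 sigma^2)) / a`` for Euclidean distance
    ``d <= radius`` from the centre and exactly zero beyond, with ``a``
    chosen so the weights sum to 1.

    Parameters
    ----------
    sigma : float
        Gaussian standard deviation in pixels; must be positive.
    radius : int
        Neighbourhood radius in pixels; must be >= 1.  The mask is
        (2*radius+1) square.
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be a positive finite real, got {sigma!r}")
    if int(radius) != radius or radius < 1:
        raise ValueError(f"radius must be a positive integer, got {radius!r}")
    radius = int(radius)

    coords = np.arange(-radius, radius + 1, dtype=float)
    dy, dx = np.meshgrid(coords, coords, indexing="ij")
    d2 = dy * dy + dx * dx
    raw = np.exp(-d2 / (2.0 * sigma * sigma))
    raw[d2 > radius * radius] = 0.0  # circular truncation inside the square mask
    a = float(raw.sum())
    return KernelMask(weights=raw / a, radius=radius, sigma=float(sigma), normalizer=a)


def local_weighted_convolve(field: np.ndarray, kernel: KernelMask) -> np.ndarray:
    """Discrete realisation of ``out(y) = sum_x omega(x - y) field(x)``.

    Zero padding outside the image: contributions from outside the domain
    vanish, so ratio-form statistics computed as quotients of two such
    convolutions renormalise themselves near boundaries.  The window is
    symmetric, so convolution and correlation coincide.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be a 2-D array")
    if kernel.weights.shape[0] > field.shape[0] or kernel.weights.shape[1] > field.shape[1]:
        raise ValueError(
            f"kernel {kernel.weights.shape} larger than image {field.shape}"
        )
    return fftconvolve(field, kernel.weights, mode="same")
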