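"""Distance kernels on the raster grid.

Distances are Euclidean, center to center, in projected metres. Kernels are
truncated at a maximum radius and applied as normalized moving averages: the
denominator is the kernel mass actually inside the grid, so a spatially
uniform field is an exact fixed point of the average (including at edges).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve


def distance_matrix(radius: float, pixel_size: float) -> np.ndarray:
    """Center-to-center distance (m) over the square footprint of ``radius``."""
    r_px = int(np.floor(radius / pixel_size))
    offsets = np.arange(-r_px, r_px + 1, dtype=float)
    return np.hypot(offsets[:, None], offsets[None, :]) * pixel_size


def exponential_kernel(alpha: float, radius: float, pixel_size: float) -> np.ndarray:
    """exp(-d/alpha), truncated (set to 0) beyond ``radius``."""
    d = distance_matrix(radius, pixel_size)
    k = np.exp(-d / alpha)
    k[d > radius] = 0.0
    return k

def linear_decay_kernel(d_max: float, pixel_size: float) -> np.ndarray:
    """1 - d/d_max, clipped to 0 beyond ``d_max``."""
    d = distance_matrix(d_max, pixel_size)
    return np.clip(1.0 - d / d_max, 0.0, None)


def exponential_decay_kernel(d_max: float, pixel_size: float) -> np.ndarray:
    """exp(-2.99 d/d_max), truncated beyond ``d_max``.

    The 2.99 factor makes the weight fall to ~5% at the maximum distance,
    the usual convention for exponential threat decay.
    """
    d = distance_matrix(d_max, pixel_size)
    k = np.exp(-2.99 * d / d_max)
    k[d > d_max] = 0.0
    return k


def disk_kernel(radius: float, pixel_size: float) -> np.ndarray:
    """Indicator of the disk of ``radius`` (center included)."""
    d = distance_matrix(radius, pixel_size)
    return (d <= radius).astype(float)


def kernel_average(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Kernel-weighted moving average with boundary-aware normalization.

    Returns ``sum_y K(d(x,y)) f(y) / sum_y K(d(x,y))`` where y ranges over
    grid pixels inside the kernel footprint (pixels outside the grid carry
    no weight).
    """
    num = convolve(field.astype(float), kernel, mode="constant", cval=0.0)
    den = convolve(np.ones_like(field, dtype=float), kernel, mode="constant", cval=0.0)
    return num / den


def kernel_average_bruteforce(field: np.ndarray, kernel_fn, radius: float,
                              pixel_size: float) -> np.ndarray:
    """Direct double loop over all pixel pairs; oracle for small grids.

    ``kernel_fn`` maps distance in metres to weight; weights beyond
    ``radius`` are dropped.
    """
    h, w = field.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            num = 0.0
            den = 0.0
            for y in range(h):
                for x in range(w):
                    d = np.hypot(i - y, j - x) * pixel_size
                    if d > radius:
                        continue
                    k = kernel_fn(d)
                    num += k * field[y, x]
                    den += k
            out[i, j] = num / den
    return out
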