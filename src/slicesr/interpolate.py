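"""Cubic through-plane interpolation shared by the pre-upsampling pipeline
and the bicubic comparator.

LR slice j sits at HR-grid coordinate ``j*step + offset`` where the offset
is the center of the first slab footprint (2.0 for 5 mm thickness on a
1 mm grid).  Interpolation uses the Keys cubic convolution kernel
(a = -0.5, the common "bicubic" kernel) with clamp-to-edge boundary
handling; the kernel is a partition of unity, so constants are preserved
exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cubic_kernel", "interp_matrix", "upsample_through_plane"]


def cubic_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    x = np.abs(np.asarray(x, dtype=np.float64))
    out = np.zeros_like(x)
    m1 = x <= 1
    out[m1] = (a + 2) * x[m1] ** 3 - (a + 3) * x[m1] ** 2 + 1
    m2 = (x > 1) & (x < 2)
    out[m2] = a * (x[m2] ** 3 - 5 * x[m2] ** 2 + 8 * x[m2] - 4)
    return out


def interp_matrix(n_lr: int, step: int, offset: float, n_hr: int) -> np.ndarray:
    """Dense (n_hr, n_lr) matrix mapping LR samples to the HR grid.

    Row t holds the cubic weights of the four LR neighbours of HR position
    t; out-of-range neighbour indices are clamped to the edge samples.
    Rows sum to 1 exactly up to float rounding.
    """
    if n_lr < 2:
        raise ValueError(f"need at least 2 LR samples, got {n_lr}")
    w = np.zeros((n_hr, n_lr), dtype=np.float64)
    t = np.arange(n_hr, dtype=np.float64)
    s = (t - offset) / step            # continuous LR coordinate per HR index
    i0 = np.floor(s).astype(int)
    f = s - i0
    for m in range(-1, 3):
        weights = cubic_kernel(f - m)
        idx = np.clip(i0 + m, 0, n_lr - 1)
        np.add.at(w, (np.arange(n_hr), idx), weights)
    return w


def upsample_through_plane(data: np.ndarray, axis: int, step: int,
                           offset: float, n_hr: int) -> np.ndarray:
    """Cubically interpolate an array along ``axis`` from LR to the HR grid."""
    n_lr = data.shape[axis]
    w = interp_matrix(n_lr, step, offset, n_hr)
    moved = np.moveaxis(np.asarray(data, dtype=np.float64), axis, -1)
    out = moved @ w.T
    return np.moveaxis(out, -1, axis)
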