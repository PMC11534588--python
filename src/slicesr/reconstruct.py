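"""HR volume reconstruction from one LR multi-slice volume.

Sliding-window inference: along each of the two in-plane axes, every
window of 3 contiguous LR planes is cubically pre-interpolated to the HR
grid along the slice axis, passed through the (scale-1) SR model as a
3-channel image, and each output channel is accumulated at its plane
position with a center-heavy window weight; per-position weights are
renormalized so boundary planes (covered by fewer windows) are still
proper averages.  The two per-axis volumes are then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .degrade import AcquisitionModel
from .interpolate import upsample_through_plane
from .volume_io import Volume

__all__ = ["FusionSpec", "sr_along_axis", "sr_volume", "fusion_weights"]


@dataclass
class FusionSpec:
    """Weights for the up-to-3 window outputs covering one plane position;
    center-heavy by default (the channel predicted with most context)."""

    window_weights: tuple = (0.25, 0.5, 0.25)
    batch_size: int = 8

    def __post_init__(self):
        self.window_weights = tuple(float(w) for w in self.window_weights)
        if len(self.window_weights) != 3 or any(w <= 0 for w in self.window_weights):
            raise ValueError("need 3 positive window weights")
        s = sum(self.window_weights)
        self.window_weights = tuple(w / s for w in self.window_weights)


def fusion_weights(n_planes: int, spec: FusionSpec | None = None):
    """Accumulated per-plane weight before and after renormalization
    (audit helper: the normalized weights are identically 1)."""
    spec = spec or FusionSpec()
    acc = np.zeros(n_planes)
    for p in range(n_planes - 2):
        for c, w in enumerate(spec.window_weights):
            acc[p + c] += w
    return acc, np.ones_like(acc)


def sr_along_axis(model, lr: Volume, acq: AcquisitionModel, axis: int,
                  spec: FusionSpec | None = None) -> Volume:
    """Reconstruct the HR volume by sliding a 3-plane window along one
    in-plane axis."""
    spec = spec or FusionSpec()
    a = acq.slice_axis
    if axis == a or axis not in (0, 1, 2):
        raise ValueError(f"axis {axis} must be one of the in-plane axes (not {a})")
    step = acq.decimation_step(min(lr.spacing))
    offset = acq.profile.center_offset
    n_planes = lr.shape[axis]
    if n_planes < 3:
        raise ValueError(f"need at least 3 planes along axis {axis}, got {n_planes}")

    # plane stack: (planes, other in-plane axis, slice axis)
    other = ({0, 1, 2} - {axis, a}).pop()
    stack = lr.data.transpose(axis, other, a)
    n_hr = stack.shape[2] * step
    up = upsample_through_plane(stack, 2, step, offset, n_hr)

    windows = np.stack([up[p : p + 3] for p in range(n_planes - 2)])  # (W,3,H,Whr)
    out_planes = np.empty_like(windows)
    for i in range(0, len(windows), spec.batch_size):
        out_planes[i : i + spec.batch_size] = model.predict(
            windows[i : i + spec.batch_size])

    acc = np.zeros((n_planes,) + up.shape[1:])
    wsum = np.zeros(n_planes)
    for p in range(n_planes - 2):
        for c, w in enumerate(spec.window_weights):
            acc[p + c] += w * out_planes[p, c]
            wsum[p + c] += w
    acc /= wsum[:, None, None]

    # back to volume axis order: current order (axis, other, a)
    inv = np.argsort((axis, other, a))
    data = acc.transpose(inv)
    voxel = min(lr.spacing)
    return Volume(data, (voxel,) * 3, lr.axes)


def sr_volume(model, lr: Volume, acq: AcquisitionModel,
              spec: FusionSpec | None = None, scale: float = 1.0) -> Volume:
    """Average the two per-axis reconstructions and undo the intensity
    normalization (``scale`` as returned by ``normalize_intensity``)."""
    spec = spec or FusionSpec()
    axes = [ax for ax in range(3) if ax != acq.slice_axis]
    vols = [sr_along_axis(model, lr, acq, ax, spec) for ax in axes]
    data = 0.5 * (vols[0].data + vols[1].data)
    if scale != 1.0:
        data = data * scale
    return Volume(data, vols[0].spacing, lr.axes)
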