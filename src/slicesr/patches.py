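"""Extraction of co-registered 3-channel LR-HR patch pairs.

SR networks for natural images take 3-channel (RGB) inputs; here the three
channels are three contiguous 2D patches along the in-plane dimension
orthogonal to the patch plane, so the models see local 3D context.  HR
patches are 96x96 in a plane that contains the slice axis; the LR
counterpart is an exact sub-grid of the simulated LR volume (96x16 or
16x96 at a decimation step of 6), so the LR-HR correspondence is lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degrade import AcquisitionModel
from .volume_io import Mask, Volume

__all__ = ["PatchPair", "ExtractionSpec", "extract_pairs", "brain_fraction",
           "save_patch_dataset", "load_patch_dataset"]


@dataclass
class PatchPair:
    """One co-registered LR-HR 3-channel patch pair plus provenance."""

    lr: np.ndarray   # (3, h, w) with h*w in {96*16, 16*96}
    hr: np.ndarray   # (3, 96, 96)
    provenance: dict = field(default_factory=dict)
    # provenance keys: volume_id, slice_axis, channel_axis, plane_axes,
    # corner (3 ints on the HR grid), step, offset, slice_dim (1 or 2:
    # which patch dimension runs along the slice axis)


@dataclass
class ExtractionSpec:
    hr_patch_size: int = 96
    n_patches: int = 18
    min_brain_fraction: float = 0.5
    max_attempts: int = 100     # rejection-sampling budget per patch
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_brain_fraction <= 1):
            raise ValueError(
                f"min brain fraction must be in (0,1], got {self.min_brain_fraction}"
            )
        if self.hr_patch_size < 1 or self.n_patches < 1 or self.max_attempts < 1:
            raise ValueError("patch size, count and attempt budget must be >= 1")


def brain_fraction(brain: Mask, corner, size: int, plane_axes, plane_index: int) -> float:
    """Fraction of brain-mask voxels in one patch plane.

    ``plane_axes`` are the two volume axes spanned by the patch;
    ``plane_index`` is the position along the remaining (channel) axis.
    """
    corner = tuple(int(c) for c in corner)
    channel_axis = ({0, 1, 2} - set(plane_axes)).pop()
    idx = [None, None, None]
    for ax in plane_axes:
        if corner[ax] < 0 or corner[ax] + size > brain.shape[ax]:
            raise IndexError(
                f"patch corner {corner} size {size} out of bounds for {brain.shape}"
            )
        idx[ax] = slice(corner[ax], corner[ax] + size)
    if plane_index < 0 or plane_index >= brain.shape[channel_axis]:
        raise IndexError(f"plane index {plane_index} out of bounds")
    idx[channel_axis] = plane_index
    plane = brain.data[tuple(idx)]
    return float(plane.sum()) / (size * size)


def _take_block(data: np.ndarray, corner, sizes) -> np.ndarray:
    sl = tuple(slice(c, c + s) for c, s in zip(corner, sizes))
    return data[sl]


def extract_pairs(hr: Volume, lr: Volume, acq: AcquisitionModel, brain: Mask,
                  spec: ExtractionSpec, volume_id: str = "") -> list[PatchPair]:
    """Randomly extract aligned 3-channel LR-HR patch pairs.

    HR patch corners along the slice axis are restricted to multiples of
    the decimation step so that the LR patch is an exact sub-grid of the
    LR volume; accepted patches have brain coverage >= min_brain_fraction
    in the central channel plane.
    """
    a = acq.slice_axis
    step = acq.decimation_step(hr.spacing[a])
    size = spec.hr_patch_size
    if size % step:
        raise ValueError(f"patch size {size} not divisible by decimation step {step}")
    if hr.shape != brain.shape:
        raise ValueError("brain mask not aligned with HR volume")
    in_plane = [ax for ax in range(3) if ax != a]
    usable_a = lr.shape[a] * step      # HR extent actually covered by LR slices
    rng = np.random.default_rng(spec.seed)
    offset = acq.profile.center_offset

    pairs: list[PatchPair] = []
    for _ in range(spec.n_patches):
        for attempt in range(spec.max_attempts):
            q = in_plane[rng.integers(2)]          # in-plane axis of the patch plane
            c_ax = in_plane[1 - in_plane.index(q)]  # channel axis
            if (usable_a < size or hr.shape[q] < size or hr.shape[c_ax] < 3):
                raise ValueError(
                    f"volume shape {hr.shape} too small for {size} patches "
                    f"with slice axis {a}"
                )
            corner = [0, 0, 0]
            corner[a] = int(rng.integers((usable_a - size) // step + 1)) * step
            corner[q] = int(rng.integers(hr.shape[q] - size + 1))
            corner[c_ax] = int(rng.integers(hr.shape[c_ax] - 2))
            frac = brain_fraction(brain, corner, size, (q, a), corner[c_ax] + 1)
            if frac >= spec.min_brain_fraction:
                break
        else:
            raise RuntimeError(
                f"could not place patch {len(pairs) + 1}/{spec.n_patches} after "
                f"{spec.max_attempts} attempts (min brain fraction "
                f"{spec.min_brain_fraction}, mask voxels {int(brain.data.sum())})"
            )
        sizes_hr = [0, 0, 0]
        sizes_hr[a], sizes_hr[q], sizes_hr[c_ax] = size, size, 3
        hr_block = _take_block(hr.data, corner, sizes_hr)
        hr_patch = np.moveaxis(hr_block, c_ax, 0)   # (3, ., .) plane axes in order

        corner_lr = list(corner)
        corner_lr[a] = corner[a] // step
        sizes_lr = list(sizes_hr)
        sizes_lr[a] = size // step
        lr_block = _take_block(lr.data, corner_lr, sizes_lr)
        lr_patch = np.moveaxis(lr_block, c_ax, 0)

        plane_axes_sorted = tuple(sorted((q, a)))
        slice_dim = 1 + plane_axes_sorted.index(a)   # 1 or 2 within the patch
        pairs.append(PatchPair(
            lr=np.ascontiguousarray(lr_patch),
            hr=np.ascontiguousarray(hr_patch),
            provenance={
                "volume_id": volume_id,
                "slice_axis": a,
                "channel_axis": c_ax,
                "plane_axes": plane_axes_sorted,
                "corner": tuple(corner),
                "step": step,
                "offset": offset,
                "slice_dim": slice_dim,
            },
        ))
    return pairs


def save_patch_dataset(path: str, pairs: list[PatchPair]):
    """Write a patch set as one array container per split plus a tabular
    provenance index (runtime artifacts, not meant for versioning)."""
    os.makedirs(path, exist_ok=True)
    np.savez(os.path.join(path, "patches.npz"),
             **{f"lr_{i}": p.lr for i, p in enumerate(pairs)},
             **{f"hr_{i}": p.hr for i, p in enumerate(pairs)})
    rows = []
    for i, p in enumerate(pairs):
        row = {"index": i}
        row.update({k: str(v) for k, v in p.provenance.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(path, "provenance.csv"), index=False)


def load_patch_dataset(path: str) -> list[PatchPair]:
    import ast

    arrs = np.load(os.path.join(path, "patches.npz"))
    prov = pd.read_csv(os.path.join(path, "provenance.csv"))
    pairs = []
    for _, row in prov.iterrows():
        i = int(row["index"])
        p = {}
        for k in ("volume_id", "slice_axis", "channel_axis", "plane_axes",
                  "corner", "step", "offset", "slice_dim"):
            if k in row:
                v = row[k]
                try:
                    p[k] = ast.literal_eval(str(v))
                except (ValueError, SyntaxError):
                    p[k] = v
        pairs.append(PatchPair(lr=arrs[f"lr_{i}"], hr=arrs[f"hr_{i}"], provenance=p))
    return pairs
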