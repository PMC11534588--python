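"""Synthetic 3D brain-like phantoms with white-matter lesions.

The phantom emulates, on a 1 mm isotropic grid, the features that matter
for testing and desk-scale training of a through-plane super-resolution
pipeline: piecewise-constant tissue classes (CSF shell, grey matter,
white matter, central CSF "ventricles") with smooth curved boundaries,
hyperintense (FLAIR-like) or hypointense (T1-like) focal lesions placed
fully inside white matter, a smooth multiplicative bias field, and
additive noise.  It is not an anatomical atlas: there is no cortical
folding and no skull; the background is air at zero intensity, as in
skull-stripped data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Mask, Volume

__all__ = ["PhantomSpec", "Phantom", "generate_phantom"]

#: tissue mean defaults per contrast mode (CSF, GM, WM, lesion)
_MODE_MEANS = {
    "flair": (0.15, 0.55, 0.40, 0.85),
    "t1": (0.15, 0.45, 0.70, 0.35),
}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    mode: str = "flair"
    csf_mean: float | None = None
    gm_mean: float | None = None
    wm_mean: float | None = None
    lesion_mean: float | None = None
    n_lesions: int = 6
    lesion_radius_mm: tuple[float, float] = (2.0, 5.0)
    bias_amplitude: float = 0.1
    noise_sigma: float = 0.01
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 48 for s in self.shape):
            raise ValueError(f"grid shape must be >= 48 per axis, got {self.shape}")
        if self.mode not in _MODE_MEANS:
            raise ValueError(f"mode must be 'flair' or 't1', got {self.mode!r}")
        defaults = _MODE_MEANS[self.mode]
        for name, d in zip(("csf_mean", "gm_mean", "wm_mean", "lesion_mean"), defaults):
            if getattr(self, name) is None:
                setattr(self, name, d)
        if self.mode == "flair" and not self.lesion_mean > self.wm_mean:
            raise ValueError("FLAIR-like mode requires lesion mean > WM mean")
        if self.mode == "t1" and not (self.wm_mean > self.gm_mean > self.csf_mean):
            raise ValueError("T1-like mode requires WM > GM > CSF means")
        lo, hi = self.lesion_radius_mm
        if not (0 < lo <= hi):
            raise ValueError(f"lesion radii must be positive, got {self.lesion_radius_mm}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class Phantom:
    volume: Volume
    brain_mask: Mask
    lesion_mask: Mask
    labels: np.ndarray          # 0 air, 1 CSF, 2 GM, 3 WM (lesion mask separate)
    lesions: list = field(default_factory=list)  # (center xyz, semi-axes mm)


# label codes
AIR, CSF, GM, WM = 0, 1, 2, 3


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float) -> np.ndarray:
    """Zero-mean low-frequency random field normalized to unit max amplitude."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_vox, mode="nearest")
    f -= f.mean()
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _ellipsoid_voxels(center, radii, shape):
    """Integer voxel coordinates inside an ellipsoid (brute-force box scan)."""
    lo = np.maximum(np.floor(np.asarray(center) - radii).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(center) + radii).astype(int) + 1,
                    np.asarray(shape))
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    rho2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    inside = rho2 <= 1.0
    return tuple(g[inside] for g in grids)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build one phantom; fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.44 * np.asarray(shape)

    # radial coordinate of the brain ellipsoid, deformed by a smooth field
    ax = [np.arange(s) for s in shape]
    grids = np.meshgrid(*ax, indexing="ij")
    rho = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))
    rho = rho + 0.06 * _smooth_field(rng, shape, sigma_vox=min(shape) / 8.0)

    labels = np.full(shape, AIR, dtype=np.uint8)
    labels[rho < 1.00] = CSF
    labels[rho < 0.92] = GM
    labels[rho < 0.74] = WM
    # central CSF cavity (ventricle-like), deformed ellipsoid around the center
    vent_semi = 0.16 * np.asarray(shape)
    rho_v = np.sqrt(sum(((g - c) / a) ** 2
                        for g, c, a in zip(grids, center, vent_semi)))
    rho_v = rho_v + 0.15 * _smooth_field(rng, shape, sigma_vox=min(shape) / 10.0)
    labels[(rho_v < 1.0) & (labels == WM)] = CSF

    brain = labels != AIR
    lesion_mask = np.zeros(shape, dtype=bool)
    lesions = []
    wm_coords = np.argwhere(labels == WM)
    max_attempts = 100 * max(spec.n_lesions, 1)
    attempts = 0
    while len(lesions) < spec.n_lesions:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place lesions: requested {spec.n_lesions}, "
                f"placed {len(lesions)} after {attempts} attempts"
            )
        attempts += 1
        c = wm_coords[rng.integers(len(wm_coords))].astype(float)
        radii = rng.uniform(*spec.lesion_radius_mm, size=3)
        vox = _ellipsoid_voxels(c, radii, shape)
        if len(vox[0]) == 0:
            continue
        if np.all(labels[vox] == WM) and not lesion_mask[vox].any():
            lesion_mask[vox] = True
            lesions.append((c, radii))

    intensity = np.zeros(shape, dtype=np.float64)
    means = {CSF: spec.csf_mean, GM: spec.gm_mean, WM: spec.wm_mean}
    for lab, mu in means.items():
        intensity[labels == lab] = mu
    intensity[lesion_mask] = spec.lesion_mean

    if spec.bias_amplitude > 0:
        bias = 1.0 + spec.bias_amplitude * _smooth_field(
            rng, shape, sigma_vox=min(shape) / 4.0)
        intensity *= bias
    if spec.noise_sigma > 0:
        if spec.noise_model == "gaussian":
            intensity = intensity + rng.normal(0.0, spec.noise_sigma, shape)
        else:  # magnitude-MRI Rician
            n1 = rng.normal(0.0, spec.noise_sigma, shape)
            n2 = rng.normal(0.0, spec.noise_sigma, shape)
            intensity = np.sqrt((intensity + n1) ** 2 + n2 ** 2)

    spacing = (1.0, 1.0, 1.0)
    return Phantom(
        volume=Volume(intensity, spacing),
        brain_mask=Mask(brain.astype(np.uint8), spacing),
        lesion_mask=Mask(lesion_mask.astype(np.uint8), spacing),
        labels=labels,
        lesions=lesions,
    )
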