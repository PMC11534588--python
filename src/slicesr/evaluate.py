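"""Image-quality metrics: brain-masked PSNR/SSIM on volumes, a patch-level
IQM suite, and a Dice utility.

Volume metrics are computed inside a brain mask so background air (uniform
in both images) cannot inflate them.  SSIM uses the canonical formulation:
local moments from a Gaussian window (sigma 1.5) with stabilization
constants K1 = 0.01, K2 = 0.03, averaged over masked voxels.

The five perceptual patch metrics (VIF, FSIM, VSI, HaarPSI, DISTS) are
delegated to an external metric provider through an adapter; when no
provider backend is importable they are reported as unavailable rather
than silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Mask, Volume

__all__ = ["IQMReport", "psnr_masked", "ssim_masked", "patch_iqm_suite",
           "dice", "aggregate_reports", "PERCEPTUAL_IQMS"]

PERCEPTUAL_IQMS = ("VIF", "FSIM", "VSI", "HaarPSI", "DISTS")

#: larger-is-better flag per metric (DISTS is a distance)
METRIC_DIRECTION = {"PSNR": True, "SSIM": True, "VIF": True, "FSIM": True,
                    "VSI": True, "HaarPSI": True, "DISTS": False}


@dataclass
class IQMReport:
    values: dict = field(default_factory=dict)       # metric -> float
    unavailable: dict = field(default_factory=dict)  # metric -> reason


def _asdata(x):
    return x.data if isinstance(x, (Volume, Mask)) else np.asarray(x)


def psnr_masked(ref, test, mask, data_range: float = 1.0) -> float:
    """10*log10(range^2 / masked MSE); +inf for identical inputs."""
    ref, test, m = _asdata(ref), _asdata(test), _asdata(mask).astype(bool)
    if ref.shape != test.shape or ref.shape != m.shape:
        raise ValueError(
            f"shape mismatch: ref {ref.shape}, test {test.shape}, mask {m.shape}"
        )
    if not m.any():
        raise ValueError("psnr_masked: mask is empty")
    mse = float(np.mean((ref[m] - test[m]) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def ssim_masked(ref, test, mask, data_range: float = 1.0,
                sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
                truncate: float = 4.0) -> float:
    """Mean of the local SSIM map over masked voxels (any dimensionality)."""
    ref, test = _asdata(ref).astype(np.float64), _asdata(test).astype(np.float64)
    m = _asdata(mask).astype(bool)
    if ref.shape != test.shape or ref.shape != m.shape:
        raise ValueError("ssim_masked: shape mismatch")
    if not m.any():
        raise ValueError("ssim_masked: mask is empty")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def win(x):
        return gaussian_filter(x, sigma, mode="nearest", truncate=truncate)

    mu_r, mu_t = win(ref), win(test)
    var_r = win(ref * ref) - mu_r ** 2
    var_t = win(test * test) - mu_t ** 2
    cov = win(ref * test) - mu_r * mu_t
    ssim_map = ((2 * mu_r * mu_t + c1) * (2 * cov + c2)) / (
        (mu_r ** 2 + mu_t ** 2 + c1) * (var_r + var_t + c2))
    return float(ssim_map[m].mean())


def _try_piq_metrics(ref: np.ndarray, test: np.ndarray) -> dict:
    """Adapter to the PyTorch Image Quality provider; raises ImportError
    when the backend is absent."""
    import torch  # noqa: F401  (provider backend)
    import piq

    r = torch.from_numpy(ref[None].astype("float32"))
    t = torch.from_numpy(test[None].astype("float32"))
    return {
        "VIF": float(piq.vif_p(t, r, data_range=1.0)),
        "FSIM": float(piq.fsim(t, r, data_range=1.0)),
        "VSI": float(piq.vsi(t, r, data_range=1.0)),
        "HaarPSI": float(piq.haarpsi(t, r, data_range=1.0)),
        "DISTS": float(piq.DISTS()(t, r)),
    }


def patch_iqm_suite(ref_patch: np.ndarray, test_patch: np.ndarray,
                    data_range: float = 1.0) -> IQMReport:
    """Full IQM report for one 3-channel patch pair in [0,1].

    PSNR and SSIM are computed in-package (full mask); the perceptual
    metrics go through the provider adapter and are marked unavailable if
    no backend exists.
    """
    ref = np.asarray(ref_patch, dtype=np.float64)
    test = np.asarray(test_patch, dtype=np.float64)
    if ref.shape != test.shape or ref.ndim != 3 or ref.shape[0] != 3:
        raise ValueError(f"expected matching (3,H,W) patches, got {ref.shape}")
    full = np.ones(ref.shape, dtype=bool)
    report = IQMReport()
    report.values["PSNR"] = psnr_masked(ref, test, full, data_range)
    report.values["SSIM"] = ssim_masked(ref, test, full, data_range)
    try:
        report.values.update(_try_piq_metrics(ref, test))
    except ImportError as exc:
        for name in PERCEPTUAL_IQMS:
            report.unavailable[name] = f"metric provider not importable: {exc}"
    except Exception as exc:  # provider failure on a specific input
        for name in PERCEPTUAL_IQMS:
            if name not in report.values:
                report.unavailable[name] = f"provider error: {exc}"
    return report


def aggregate_reports(reports: list[IQMReport]) -> dict:
    """Mean and standard deviation per metric over an image set."""
    out = {}
    names = sorted({k for r in reports for k in r.values})
    for name in names:
        vals = np.array([r.values[name] for r in reports if name in r.values])
        finite = vals[np.isfinite(vals)]
        out[name] = {
            "mean": float(finite.mean()) if finite.size else math.inf,
            "sd": float(finite.std(ddof=1)) if finite.size > 1 else 0.0,
            "n": int(vals.size),
        }
    return out


def dice(a, b) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a, b = _asdata(a).astype(bool), _asdata(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("dice: shape mismatch")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
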