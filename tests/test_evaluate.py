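import math

import numpy as np
import pytest

import slicesr as S


def full_mask(shape):
    return S.Mask(np.ones(shape, dtype=np.uint8), (1, 1, 1))


def test_psnr_constant_offset_analytic(rng):
    ref = rng.random((10, 10, 10)) * 0.5
    assert S.psnr_masked(ref, ref + 0.1, full_mask(ref.shape), 1.0) == \
        pytest.approx(20.0, abs=1e-10)


def test_psnr_identical_inputs_infinite(rng):
    ref = rng.random((8, 8, 8))
    assert math.isinf(S.psnr_masked(ref, ref, full_mask(ref.shape)))


def test_psnr_matches_masked_mse_loop(rng):
    ref, test = rng.random((8, 8, 8)), rng.random((8, 8, 8))
    mask = rng.random((8, 8, 8)) > 0.5
    total, n = 0.0, 0
    for idx in np.ndindex(ref.shape):
        if mask[idx]:
            total += (ref[idx] - test[idx]) ** 2
            n += 1
    expected = 10 * math.log10(1.0 / (total / n))
    m = S.Mask(mask.astype(np.uint8), (1, 1, 1))
    assert S.psnr_masked(ref, test, m) == pytest.approx(expected, rel=1e-12)


def test_psnr_empty_mask_errors(rng):
    ref = rng.random((6, 6, 6))
    with pytest.raises(ValueError, match="empty"):
        S.psnr_masked(ref, ref, S.Mask(np.zeros((6, 6, 6), dtype=np.uint8),
                                       (1, 1, 1)))


def test_psnr_decreases_with_noise(rng):
    ref = rng.random((12, 12, 12))
    m = full_mask(ref.shape)
    values = [S.psnr_masked(ref, ref + rng.normal(0, s, ref.shape), m)
              for s in (0.01, 0.03, 0.1, 0.3)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_ssim_identity_is_one(rng):
    ref = rng.random((10, 10, 10))
    assert S.ssim_masked(ref, ref, full_mask(ref.shape)) == pytest.approx(1.0)


def test_ssim_inverted_image_below_one(rng):
    ref = rng.random((10, 10, 10))
    assert S.ssim_masked(ref, 1 - ref, full_mask(ref.shape)) < 1.0


def test_ssim_symmetric(rng):
    a, b = rng.random((10, 10, 10)), rng.random((10, 10, 10))
    m = full_mask(a.shape)
    assert S.ssim_masked(a, b, m) == pytest.approx(S.ssim_masked(b, a, m))


def test_ssim_interior_matches_hand_moments(rng):
    """At a voxel whose Gaussian window lies fully inside the volume, the
    local SSIM value equals the moment formula computed with hand-built
    Gaussian weights."""
    shape = (15, 15, 15)
    ref, test = rng.random(shape), rng.random(shape)
    sigma, c = 1.5, (7, 7, 7)
    r = int(4 * sigma + 0.5)
    g1 = np.exp(-0.5 * (np.arange(-r, r + 1) / sigma) ** 2)
    g1 /= g1.sum()
    w = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    box = tuple(slice(ci - r, ci + r + 1) for ci in c)

    def mom(x):
        return float(np.sum(w * x[box]))

    mu_r, mu_t = mom(ref), mom(test)
    var_r = mom(ref * ref) - mu_r ** 2
    var_t = mom(test * test) - mu_t ** 2
    cov = mom(ref * test) - mu_r * mu_t
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    expected = ((2 * mu_r * mu_t + c1) * (2 * cov + c2)) / (
        (mu_r ** 2 + mu_t ** 2 + c1) * (var_r + var_t + c2))

    single = np.zeros(shape, dtype=np.uint8)
    single[c] = 1
    got = S.ssim_masked(ref, test, S.Mask(single, (1, 1, 1)))
    assert got == pytest.approx(expected, rel=1e-6)


def test_ssim_interior_matches_skimage(rng):
    """Independent cross-check: deep-interior SSIM map values agree with
    scikit-image's Gaussian-weighted implementation."""
    from skimage.metrics import structural_similarity

    shape = (18, 18, 18)
    ref, test = rng.random(shape), rng.random(shape)
    _, sk_map = structural_similarity(
        ref, test, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, data_range=1.0, full=True)
    interior = np.zeros(shape, dtype=np.uint8)
    interior[7:-7, 7:-7, 7:-7] = 1
    mine = S.ssim_masked(ref, test, S.Mask(interior, (1, 1, 1)), truncate=3.5)
    theirs = float(sk_map[interior.astype(bool)].mean())
    assert mine == pytest.approx(theirs, rel=1e-7)


def test_patch_iqm_identity_values(rng):
    patch = rng.random((3, 32, 32))
    report = S.patch_iqm_suite(patch, patch)
    assert math.isinf(report.values["PSNR"])
    assert report.values["SSIM"] == pytest.approx(1.0)
    # every requested metric is either computed or explicitly unavailable
    covered = set(report.values) | set(report.unavailable)
    assert {"PSNR", "SSIM", "VIF", "FSIM", "VSI", "HaarPSI", "DISTS"} <= covered
    if "DISTS" in report.values:
        assert report.values["DISTS"] == pytest.approx(0.0, abs=1e-5)


def test_patch_iqm_psnr_consistent_with_masked(rng):
    a, b = rng.random((3, 16, 16)), rng.random((3, 16, 16))
    report = S.patch_iqm_suite(a, b)
    expected = S.psnr_masked(a, b, S.Mask(np.ones((3, 16, 16), dtype=np.uint8),
                                          (1, 1, 1)))
    assert report.values["PSNR"] == pytest.approx(expected)


def test_aggregation_matches_brute_force(rng):
    reports = []
    for _ in range(5):
        a, b = rng.random((3, 8, 8)), rng.random((3, 8, 8))
        reports.append(S.patch_iqm_suite(a, b))
    agg = S.aggregate_reports(reports)
    vals = [r.values["SSIM"] for r in reports]
    assert agg["SSIM"]["mean"] == pytest.approx(np.mean(vals))
    assert agg["SSIM"]["sd"] == pytest.approx(np.std(vals, ddof=1))


def test_dice_overlap(rng):
    a = np.zeros((8, 8, 8), dtype=bool)
    b = np.zeros((8, 8, 8), dtype=bool)
    a[:4], b[2:6] = True, True
    assert S.dice(a, b) == pytest.approx(2 * (2 * 64) / (4 * 64 + 4 * 64))
    assert S.dice(a, a) == 1.0
    assert S.dice(a, ~a) == 0.0
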