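import numpy as np
import pytest
from scipy.signal import correlate2d

import slicesr as S
from slicesr import nn


def tiny_cfg(**kw):
    base = dict(arch="edsr", n_blocks=2, n_features=8, scale=1)
    base.update(kw)
    return S.ModelConfig(**base)


def test_tiny_edsr_parameter_count_closed_form():
    """Layer-by-layer arithmetic for a 2-block, 8-feature scale-1 EDSR."""
    m = S.build_model(tiny_cfg())
    conv = lambda ci, co: ci * co * 9 + co
    expected = conv(3, 8) + 2 * 2 * conv(8, 8) + conv(8, 8) + conv(8, 3)
    assert m.parameter_count == expected


def test_tiny_rrdb_parameter_count_closed_form():
    m = S.build_model(S.ModelConfig(arch="rrdb_generator", n_blocks=1,
                                    n_features=8, growth_channels=4, scale=1))
    conv = lambda ci, co: ci * co * 9 + co
    dense = conv(8, 4) + conv(12, 4) + conv(16, 4) + conv(20, 4) + conv(24, 8)
    expected = conv(3, 8) + 3 * dense + conv(8, 8) + conv(8, 8) + conv(8, 3)
    assert m.parameter_count == expected


def test_forward_shape_scale1_and_pixelshuffle(rng):
    m1 = S.build_model(tiny_cfg())
    x = rng.random((2, 3, 24, 24))
    assert m1.predict(x).shape == (2, 3, 24, 24)
    m2 = S.build_model(tiny_cfg(scale=2))
    assert m2.predict(x).shape == (2, 3, 48, 48)
    m3 = S.build_model(S.ModelConfig(arch="rrdb_generator", n_blocks=1,
                                     n_features=8, growth_channels=4, scale=4))
    assert m3.predict(x).shape == (2, 3, 96, 96)


def test_inference_deterministic(rng):
    m = S.build_model(tiny_cfg(), seed=4)
    x = rng.random((1, 3, 16, 16))
    np.testing.assert_array_equal(m.predict(x), m.predict(x))


def test_wrong_channel_count_rejected(rng):
    m = S.build_model(tiny_cfg())
    with pytest.raises(ValueError, match="N, 3"):
        m.predict(rng.random((1, 4, 16, 16)))


def test_untrained_scale1_is_interpolation_identity(rng):
    """Zero-initialized final conv: the pre-upsampled network starts as
    the identity on its (already interpolated) input."""
    x = rng.random((1, 3, 12, 12))
    for cfg in (tiny_cfg(), S.ModelConfig(arch="rrdb_generator", n_blocks=1,
                                          n_features=8, growth_channels=4,
                                          scale=1)):
        m = S.build_model(cfg, seed=1)
        np.testing.assert_allclose(m.predict(x), x, atol=1e-12)


def test_zeroed_residual_blocks_reduce_to_conv_chain(rng):
    """With all residual-block weights zeroed, scale-1 EDSR degenerates to
    input + tail(body_conv(head(x)) + head(x)); verified against an
    independent direct-convolution evaluation on a small input."""
    m = S.build_model(tiny_cfg(), seed=2)
    for blk in m.module.body:
        for conv in (blk.conv1, blk.conv2):
            conv.weight.data[...] = 0
            conv.bias.data[...] = 0
    m.module.tail.weight.data[...] = rng.normal(size=m.module.tail.weight.shape) * 0.1
    x = rng.random((1, 3, 5, 5))

    def direct_conv(inp, w, b):
        out = np.stack([
            sum(correlate2d(inp[c], w[o, c], mode="same") for c in range(w.shape[1]))
            + b[o] for o in range(w.shape[0])])
        return out

    head = direct_conv(x[0], m.module.head.weight.data, m.module.head.bias.data)
    trunk = direct_conv(head, m.module.body_conv.weight.data,
                        m.module.body_conv.bias.data) + head
    expected = x[0] + direct_conv(trunk, m.module.tail.weight.data,
                                  m.module.tail.bias.data)
    np.testing.assert_allclose(m.predict(x)[0], expected, atol=1e-10)


def test_fully_convolutional_stitching(rng):
    """Away from a boundary margin, forward on a wide input equals forward
    on overlapping halves."""
    m = S.build_model(tiny_cfg(), seed=3)
    rng2 = np.random.default_rng(8)
    for p in m.module.parameters():
        p.data += 0.05 * rng2.normal(size=p.data.shape)  # break the identity init
    x = rng.random((1, 3, 24, 48))
    full = m.predict(x)
    left = m.predict(x[:, :, :, :32])
    right = m.predict(x[:, :, :, 16:])
    np.testing.assert_allclose(full[..., :20], left[..., :20], atol=1e-8)
    np.testing.assert_allclose(full[..., 28:], right[..., 12:], atol=1e-8)


def test_parameter_count_invariant_to_weights():
    m = S.build_model(tiny_cfg(), seed=0)
    n0 = m.parameter_count
    for p in m.module.parameters():
        p.data[...] = 7.0
    assert m.parameter_count == n0


def test_discriminator_logit_map(rng):
    d = S.build_model(S.ModelConfig(arch="unet_discriminator", n_features=4))
    x = rng.random((2, 3, 16, 16))
    out = d.predict(x)
    assert out.shape == (2, 1, 16, 16)
    assert np.all(np.isfinite(out))


def test_checkpoint_roundtrip(tmp_path, rng):
    m = S.build_model(tiny_cfg(), seed=5)
    path = str(tmp_path / "ckpt.npz")
    S.save_checkpoint(path, m)
    m2 = S.build_model(tiny_cfg(), seed=6)
    m2, report = S.load_pretrained(m2, path)
    assert report["skipped"] == [] and report["missing"] == []
    x = rng.random((1, 3, 8, 8))
    np.testing.assert_array_equal(m.predict(x), m2.predict(x))


def test_partial_load_skips_upsampler(tmp_path):
    big = S.build_model(tiny_cfg(scale=2), seed=0)
    path = str(tmp_path / "x2.npz")
    S.save_checkpoint(path, big)
    small = S.build_model(tiny_cfg(scale=1), seed=1)
    small, report = S.load_pretrained(small, path)
    skipped_names = [n for n, _ in report["skipped"]]
    assert any("upsample" in n for n in skipped_names)
    assert any("head" in n for n in report["loaded"])


def test_matched_count_equals_shape_dict_intersection(tmp_path):
    big = S.build_model(tiny_cfg(scale=2), seed=0)
    small = S.build_model(tiny_cfg(scale=1), seed=1)
    ckpt = big.module.state_dict()
    own = {k: v.data.shape for k, v in small.module.named_parameters()}
    expected = sum(1 for k, v in ckpt.items()
                   if k in own and own[k] == v.shape)
    _, report = S.load_pretrained(small, ckpt)
    assert len(report["loaded"]) == expected


def test_zero_match_checkpoint_errors():
    m = S.build_model(tiny_cfg())
    with pytest.raises(ValueError, match="zero"):
        S.load_pretrained(m, {"nonsense": np.zeros((2, 2))})


def test_full_size_configs_validate():
    with pytest.raises(ValueError):
        S.ModelConfig(arch="nope")
    with pytest.raises(ValueError):
        S.ModelConfig(arch="edsr", scale=5)
    with pytest.raises(ValueError):
        S.build_model(S.ModelConfig(arch="unet_discriminator", scale=2))
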