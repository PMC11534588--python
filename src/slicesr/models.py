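"""SR network architectures: EDSR, the RRDB generator, and a U-Net
discriminator with spectral normalization.

Both generators are fully convolutional.  Two scale modes exist:

* ``scale > 1`` — the native pixel-shuffle upsampling head (x2/x3/x4) of
  the published architectures; used for parameter-count checks and
  isotropic experimentation.
* ``scale == 1`` — pre-upsampled mode for the anisotropic through-plane
  factor: the LR input is first cubically interpolated to the HR grid,
  the upsampling head is removed, and the network predicts a residual
  that is added to its input (zero-initialized final convolution, so an
  untrained network is exactly the interpolation identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["ModelConfig", "SRModel", "build_model", "IdentitySRModel",
           "save_checkpoint", "load_pretrained"]

ARCHS = ("edsr", "rrdb_generator", "unet_discriminator")


@dataclass
class ModelConfig:
    arch: str = "edsr"
    n_blocks: int | None = None       # EDSR default 32; RRDB default 23
    n_features: int | None = None     # EDSR default 256; RRDB default 64
    growth_channels: int = 32         # RRDB dense-block growth
    res_scale: float = 0.1            # EDSR residual scaling
    scale: int = 1                    # 1 (pre-upsampled) or 2/3/4 (pixel shuffle)
    in_channels: int = 3
    out_channels: int = 3

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}, got {self.arch!r}")
        if self.n_blocks is None:
            self.n_blocks = {"edsr": 32, "rrdb_generator": 23}.get(self.arch, 0)
        if self.n_features is None:
            self.n_features = {"edsr": 256, "rrdb_generator": 64,
                               "unet_discriminator": 64}[self.arch]
        for name in ("n_blocks", "n_features", "growth_channels", "scale",
                     "in_channels", "out_channels"):
            v = getattr(self, name)
            if int(v) != v or v < 0 or (v < 1 and name != "n_blocks"):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.scale not in (1, 2, 3, 4):
            raise ValueError(f"scale must be 1, 2, 3 or 4, got {self.scale}")


# ---------------------------------------------------------------- EDSR --

class _ResBlock(nn.Module):
    def __init__(self, feat, res_scale, rng):
        self.conv1 = nn.Conv2d(feat, feat, 3, rng=rng)
        self.conv2 = nn.Conv2d(feat, feat, 3, rng=rng)
        self.res_scale = res_scale

    def forward(self, x):
        return x + self.res_scale * self.conv2(nn.relu(self.conv1(x)))


class _EDSR(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        f, s = cfg.n_features, cfg.scale
        self.head = nn.Conv2d(cfg.in_channels, f, 3, rng=rng)
        self.body = [_ResBlock(f, cfg.res_scale, rng) for _ in range(cfg.n_blocks)]
        self.body_conv = nn.Conv2d(f, f, 3, rng=rng)
        self.upsample = []
        if s == 3:
            self.upsample.append(nn.Conv2d(f, f * 9, 3, rng=rng))
        else:
            for _ in range(int(np.log2(s)) if s > 1 else 0):
                self.upsample.append(nn.Conv2d(f, f * 4, 3, rng=rng))
        self.tail = nn.Conv2d(f, cfg.out_channels, 3, rng=rng)
        self.scale = s
        self.image_residual = s == 1
        if self.image_residual:
            self.tail.weight.data[...] = 0.0   # start at the interpolation identity

    def forward(self, x):
        h = self.head(x)
        b = h
        for blk in self.body:
            b = blk(b)
        b = self.body_conv(b) + h              # global feature skip
        for up in self.upsample:
            b = nn.pixel_shuffle(up(b), 3 if self.scale == 3 else 2)
        out = self.tail(b)
        if self.image_residual:
            out = out + x
        return out


# ---------------------------------------------------------------- RRDB --

class _DenseBlock(nn.Module):
    def __init__(self, feat, growth, rng):
        # small-magnitude init stabilizes very deep dense trunks
        self.c1 = nn.Conv2d(feat, growth, 3, rng=rng, init_scale=0.1)
        self.c2 = nn.Conv2d(feat + growth, growth, 3, rng=rng, init_scale=0.1)
        self.c3 = nn.Conv2d(feat + 2 * growth, growth, 3, rng=rng, init_scale=0.1)
        self.c4 = nn.Conv2d(feat + 3 * growth, growth, 3, rng=rng, init_scale=0.1)
        self.c5 = nn.Conv2d(feat + 4 * growth, feat, 3, rng=rng, init_scale=0.1)

    def forward(self, x):
        lr = nn.leaky_relu
        x1 = lr(self.c1(x))
        x2 = lr(self.c2(nn.concat([x, x1])))
        x3 = lr(self.c3(nn.concat([x, x1, x2])))
        x4 = lr(self.c4(nn.concat([x, x1, x2, x3])))
        x5 = self.c5(nn.concat([x, x1, x2, x3, x4]))
        return x + 0.2 * x5


class _RRDB(nn.Module):
    def __init__(self, feat, growth, rng):
        self.db1 = _DenseBlock(feat, growth, rng)
        self.db2 = _DenseBlock(feat, growth, rng)
        self.db3 = _DenseBlock(feat, growth, rng)

    def forward(self, x):
        return x + 0.2 * self.db3(self.db2(self.db1(x)))


class _RRDBNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng):
        f, g, s = cfg.n_features, cfg.growth_channels, cfg.scale
        self.conv_first = nn.Conv2d(cfg.in_channels, f, 3, rng=rng)
        self.body = [_RRDB(f, g, rng) for _ in range(cfg.n_blocks)]
        self.conv_body = nn.Conv2d(f, f, 3, rng=rng)
        self.upconvs = [nn.Conv2d(f, f, 3, rng=rng)
                        for _ in range(int(np.log2(s)) if s in (2, 4) else (1 if s == 3 else 0))]
        self.conv_hr = nn.Conv2d(f, f, 3, rng=rng)
        self.conv_last = nn.Conv2d(f, cfg.out_channels, 3, rng=rng)
        self.scale = s
        self.image_residual = s == 1
        if self.image_residual:
            self.conv_last.weight.data[...] = 0.0

    def forward(self, x):
        h = self.conv_first(x)
        b = h
        for blk in self.body:
            b = blk(b)
        b = self.conv_body(b) + h
        for up in self.upconvs:
            b = nn.leaky_relu(up(nn.upsample_nearest2(b)))
        out = self.conv_last(nn.leaky_relu(self.conv_hr(b)))
        if self.image_residual:
            out = out + x
        return out


# ------------------------------------------------- U-Net discriminator --

class _UNetDiscriminator(nn.Module):
    """Per-pixel real/fake logits with a spectrally normalized U-Net."""

    def __init__(self, cfg: ModelConfig, rng):
        f = cfg.n_features
        SN = nn.SpectralConv2d
        self.conv0 = nn.Conv2d(cfg.in_channels, f, 3, rng=rng)
        self.down1 = SN(f, 2 * f, 4, stride=2, pad=1, rng=rng)
        self.down2 = SN(2 * f, 4 * f, 4, stride=2, pad=1, rng=rng)
        self.down3 = SN(4 * f, 8 * f, 4, stride=2, pad=1, rng=rng)
        self.up3 = SN(8 * f, 4 * f, 3, rng=rng)
        self.up2 = SN(4 * f, 2 * f, 3, rng=rng)
        self.up1 = SN(2 * f, f, 3, rng=rng)
        self.conv_hr = SN(f, f, 3, rng=rng)
        self.conv_out = nn.Conv2d(f, 1, 3, rng=rng)

    def forward(self, x):
        lr = nn.leaky_relu
        x0 = lr(self.conv0(x))
        x1 = lr(self.down1(x0))
        x2 = lr(self.down2(x1))
        x3 = lr(self.down3(x2))
        u3 = lr(self.up3(nn.upsample_nearest2(x3))) + x2
        u2 = lr(self.up2(nn.upsample_nearest2(u3))) + x1
        u1 = lr(self.up1(nn.upsample_nearest2(u2))) + x0
        return self.conv_out(lr(self.conv_hr(u1)))


# ------------------------------------------------------------- wrapper --

class SRModel:
    """Architecture config + weights, with batched inference helpers."""

    def __init__(self, config: ModelConfig, module: nn.Module):
        self.config = config
        self.module = module

    @property
    def parameter_count(self) -> int:
        return self.module.parameter_count()

    def forward(self, batch) -> nn.Tensor:
        """Graph-building forward on a Tensor or array (N, C, H, W)."""
        t = batch if isinstance(batch, nn.Tensor) else nn.Tensor(batch)
        if t.data.ndim != 4 or t.data.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, H, W), got {t.data.shape}"
            )
        out = self.module(t)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite values in model output")
        return out

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference-mode forward returning a plain array."""
        with nn.no_grad():
            return self.forward(np.asarray(batch, dtype=np.float64)).data


class IdentitySRModel:
    """Pass-through model (scale 1); useful as a reconstruction baseline."""

    config = ModelConfig(arch="edsr", n_blocks=0, n_features=1, scale=1)
    parameter_count = 0

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.asarray(batch, dtype=np.float64)


def build_model(c: ModelConfig, seed: int = 0) -> SRModel:
    """Instantiate an architecture from its configuration."""
    rng = np.random.default_rng(seed)
    if c.arch == "edsr":
        module = _EDSR(c, rng)
    elif c.arch == "rrdb_generator":
        if c.scale == 3:
            raise ValueError("rrdb_generator supports scales 1, 2 and 4")
        module = _RRDBNet(c, rng)
    else:
        if c.scale != 1:
            raise ValueError("discriminator has no upsampling scale")
        module = _UNetDiscriminator(c, rng)
    return SRModel(c, module)


# ---------------------------------------------------------- checkpoints --

def save_checkpoint(path: str, model: SRModel):
    np.savez(path, **model.module.state_dict())


def load_pretrained(model: SRModel, checkpoint: str | dict):
    """Shape-matched partial loading of a name->array checkpoint.

    Parameters whose names and shapes match are loaded; mismatches and
    absences are enumerated in the returned report.  Raises if nothing
    matches at all.
    """
    if isinstance(checkpoint, (str, bytes)):
        with np.load(checkpoint) as z:
            state = {k: z[k] for k in z.files}
    else:
        state = dict(checkpoint)
    own = dict(model.module.named_parameters())
    loaded, skipped = [], []
    for name, arr in state.items():
        if name not in own:
            skipped.append((name, "no such parameter"))
        elif own[name].data.shape != arr.shape:
            skipped.append((name, f"shape {arr.shape} vs {own[name].data.shape}"))
        else:
            own[name].data[...] = arr
            loaded.append(name)
    missing = [n for n in own if n not in state]
    if not loaded:
        raise ValueError("checkpoint matched zero parameters")
    return model, {"loaded": loaded, "skipped": skipped, "missing": missing}
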