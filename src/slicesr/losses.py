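"""Content loss (perceptual + eta * L1) and adversarial terms.

The content loss guiding fine-tuning is

    L_c = L_perceptual + eta * L_1

where L_1 is the mean absolute pixel difference and L_perceptual is a
weighted sum of mean absolute differences between feature maps of the two
images, extracted stage-by-stage by a frozen feature provider.  The
provider is injectable: the canonical choice in the GAN SR literature is
five pre-activation stages of a pretrained VGG-19 with stage weights
(0.1, 0.1, 1.0, 1.0, 1.0); this package ships deterministic self-contained
providers (identity, and a fixed multi-scale gradient pyramid) so that
training and tests need no external weights.

The adversarial term for the GAN variant is per-pixel sigmoid binary
cross-entropy on the U-Net discriminator's logit map, and the generator
objective is assembled as L_c + lambda * L_GAN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "LossConfig",
    "IdentityFeatureProvider",
    "PyramidFeatureProvider",
    "l1_loss",
    "perceptual_loss",
    "content_loss",
    "gan_losses",
    "generator_objective",
]

DEFAULT_STAGE_WEIGHTS = (0.1, 0.1, 1.0, 1.0, 1.0)


class IdentityFeatureProvider:
    """Returns the image itself at every stage (reduces L_perceptual to a
    weighted multiple of L_1); the standard provider stub for testing."""

    def __init__(self, n_stages: int = 1):
        self.n_stages = n_stages

    def __call__(self, x):
        return [x] * self.n_stages


class PyramidFeatureProvider:
    """Fixed multi-scale intensity/gradient features from frozen convolutions.

    Stage k sees the image average-pooled k times and filtered by a frozen
    bank (identity-like smoothing plus two orthogonal derivative kernels
    per channel).  Deterministic, trainable-parameter free, and cheap; a
    lightweight stand-alone choice of perceptual feature stack.
    """

    def __init__(self, n_stages: int = 5, channels: int = 3):
        self.n_stages = n_stages
        sobel_x = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64) / 8
        sobel_y = sobel_x.T
        smooth = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float64) / 16
        w = np.zeros((3 * channels, channels, 3, 3))
        for c in range(channels):
            w[3 * c, c] = smooth
            w[3 * c + 1, c] = sobel_x
            w[3 * c + 2, c] = sobel_y
        self._weight = nn.Tensor(w)          # frozen: requires_grad stays False

    def __call__(self, x):
        feats = []
        cur = x
        for k in range(self.n_stages):
            feats.append(nn.conv2d(cur, self._weight, None))
            if k < self.n_stages - 1:
                cur = nn.avg_pool2(cur)
        return feats


@dataclass
class LossConfig:
    eta: float = 1.0                       # L1 weight in the content loss
    lambda_adv: float = 0.05               # adversarial weight (GAN variant)
    stage_weights: tuple = DEFAULT_STAGE_WEIGHTS
    provider: object = None                # FeatureProvider; defaults to pyramid

    def __post_init__(self):
        if self.eta < 0 or self.lambda_adv < 0:
            raise ValueError("eta and lambda must be >= 0")
        self.stage_weights = tuple(float(w) for w in self.stage_weights)
        if len(self.stage_weights) == 0 or any(w < 0 for w in self.stage_weights):
            raise ValueError("need at least one non-negative stage weight")
        if self.provider is None:
            self.provider = PyramidFeatureProvider(n_stages=len(self.stage_weights))


def _as_tensor(x):
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=np.float64))


def l1_loss(a, b) -> nn.Tensor:
    """Mean absolute elementwise difference."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"l1_loss: shape mismatch {a.data.shape} vs {b.data.shape}")
    return nn.mean(nn.absolute(a - b))


def perceptual_loss(a, b, cfg: LossConfig) -> nn.Tensor:
    """Sum over stages of stage_weight * L1 between provider features."""
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.shape != b.data.shape:
        raise ValueError("perceptual_loss: shape mismatch")
    fa, fb = cfg.provider(a), cfg.provider(b)
    if len(fa) != len(cfg.stage_weights) or len(fb) != len(cfg.stage_weights):
        raise ValueError(
            f"provider returned {len(fa)} stages, config expects "
            f"{len(cfg.stage_weights)}"
        )
    total = None
    for w, xa, xb in zip(cfg.stage_weights, fa, fb):
        term = w * nn.mean(nn.absolute(xa - xb))
        total = term if total is None else total + term
    return total


def content_loss(a, b, cfg: LossConfig) -> nn.Tensor:
    """L_c = L_perceptual + eta * L_1."""
    return perceptual_loss(a, b, cfg) + cfg.eta * l1_loss(a, b)


def gan_losses(real_logits, fake_logits):
    """(generator adversarial term, discriminator loss).

    Both are per-pixel sigmoid BCE averaged over the logit map: the
    generator term scores fake logits against the real label; the
    discriminator loss is BCE(real, 1) + BCE(fake, 0).  The caller detaches
    fake logits from the generator graph for the discriminator update.
    """
    real_logits, fake_logits = _as_tensor(real_logits), _as_tensor(fake_logits)
    if real_logits.data.shape != fake_logits.data.shape:
        raise ValueError("gan_losses: logit map shape mismatch")
    g_loss = nn.bce_with_logits_mean(fake_logits, 1.0)
    d_loss = nn.bce_with_logits_mean(real_logits, 1.0) + \
        nn.bce_with_logits_mean(fake_logits, 0.0)
    return g_loss, d_loss


def generator_objective(sr, hr, fake_logits, cfg: LossConfig) -> nn.Tensor:
    """Full GAN generator objective L_c + lambda * L_GAN."""
    adv = nn.bce_with_logits_mean(_as_tensor(fake_logits), 1.0)
    return content_loss(sr, hr, cfg) + cfg.lambda_adv * adv
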