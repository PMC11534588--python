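"""Module/parameter containers and the layers used by the SR networks."""

from __future__ import annotations

import math

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Lightweight parameter container with recursive discovery.

    Submodules are found in instance attributes (including lists of
    modules); parameters are ``Tensor`` attributes with requires_grad=True.
    """

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict, strict: bool = True):
        own = dict(self.named_parameters())
        missing = [k for k in own if k not in state]
        unexpected = [k for k in state if k not in own]
        mismatched = [
            k for k in own
            if k in state and own[k].data.shape != np.asarray(state[k]).shape
        ]
        if strict and (missing or unexpected or mismatched):
            raise ValueError(
                f"state mismatch: missing={missing} unexpected={unexpected} "
                f"shape-mismatch={mismatched}"
            )
        for k, p in own.items():
            if k in state and k not in mismatched:
                p.data[...] = np.asarray(state[k], dtype=np.float64)
        return {"missing": missing, "unexpected": unexpected,
                "mismatched": mismatched}

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """Same-padded square-kernel convolution (stride configurable)."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 init_scale: float = 1.0):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * k * k
        std = init_scale * math.sqrt(2.0 / fan_in)  # Kaiming-normal for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, size=(out_ch, in_ch, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        pad=self.pad)


class SpectralConv2d(Conv2d):
    """Conv2d whose weight is divided by its leading singular value.

    One power iteration per forward pass during training (vectors frozen in
    inference mode), as in standard spectral normalization for GAN
    discriminators.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        o = self.weight.data.shape[0]
        rng = np.random.default_rng(12345 + o)
        self._u = rng.normal(size=o)
        self._u /= np.linalg.norm(self._u)

    def forward(self, x):
        wmat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        if T.is_grad_enabled():
            v = wmat.T @ self._u
            v /= np.linalg.norm(v) + 1e-12
            u = wmat @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u = u
        else:
            u = self._u
            v = wmat.T @ u
            v /= np.linalg.norm(v) + 1e-12
        sigma = float(u @ wmat @ v)
        wbar = T.spectral_scale(self.weight, u, v, sigma)
        return T.conv2d(x, wbar, self.bias, stride=self.stride, pad=self.pad)
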