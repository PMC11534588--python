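"""Fine-tuning of SR models on LR-HR patch pairs.

Optimization uses Adam with cosine annealing and warm restarts stepped per
epoch, the content loss L_c = L_perceptual + eta * L_1 as the objective,
and selection of the weight snapshot with minimum validation L_c.  The
GAN variant alternates one discriminator step with one generator step per
batch; model selection still uses validation L_c alone (the adversarial
term is excluded from the selection criterion).

Printed defaults mirror the fine-tuning recipe this package implements:
EDSR lr0 = 2e-4, T0 = 8, T_mult = 2; generator lr0 = 1e-4, T0 = 6,
T_mult = 1; discriminator lr0 = 5e-6, T0 = 8, T_mult = 2; batch size 6;
100 epochs; lambda = 0.05.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .interpolate import upsample_through_plane
from .losses import LossConfig, content_loss, gan_losses
from .models import SRModel

__all__ = ["TrainConfig", "TrainState", "scheduled_lr", "finetune",
           "finetune_gan", "pairs_to_arrays"]


@dataclass
class TrainConfig:
    lr0: float = 2e-4
    t0: int = 8
    t_mult: int = 2
    batch_size: int = 6
    epochs: int = 100
    betas: tuple = (0.9, 0.999)
    lr_floor: float = 1e-7
    seed: int = 0
    # GAN variant: discriminator schedule
    disc_lr0: float = 5e-6
    disc_t0: int = 8
    disc_t_mult: int = 2

    def __post_init__(self):
        if self.lr0 <= 0 or self.t0 < 1 or self.t_mult < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class TrainState:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = math.inf
    best_state: dict = field(default_factory=dict)


def scheduled_lr(progress: float, lr0: float, t0: int, t_mult: int,
                 floor: float = 1e-7) -> float:
    """Cosine annealing with warm restarts, stepped in epochs.

    Cycle lengths are T0, T0*T_mult, T0*T_mult^2, ...; within a cycle
    lr = floor + (lr0 - floor) * (1 + cos(pi * T_cur / T_i)) / 2,
    so the rate returns to lr0 exactly at each restart.
    """
    if progress < 0 or lr0 <= 0 or t0 < 1 or t_mult < 1:
        raise ValueError("invalid schedule parameters")
    t_cur = float(progress)
    t_i = float(t0)
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= t_mult
    return floor + (lr0 - floor) * (1.0 + math.cos(math.pi * t_cur / t_i)) / 2.0


def pairs_to_arrays(pairs):
    """Pre-interpolate LR patches to the HR grid and stack the set.

    Returns (X, Y): X holds the cubically upsampled 3-channel LR patches,
    Y the HR targets, both (N, 3, 96, 96).
    """
    xs, ys = [], []
    for p in pairs:
        step = int(p.provenance["step"])
        offset = float(p.provenance["offset"])
        slice_dim = int(p.provenance["slice_dim"])
        n_hr = p.hr.shape[slice_dim]
        xs.append(upsample_through_plane(p.lr, slice_dim, step, offset, n_hr))
        ys.append(np.asarray(p.hr, dtype=np.float64))
    return np.stack(xs), np.stack(ys)


def _as_arrays(dataset):
    if isinstance(dataset, tuple):
        return np.asarray(dataset[0]), np.asarray(dataset[1])
    return pairs_to_arrays(dataset)


def _validation_loss(model: SRModel, xv, yv, loss_cfg, batch_size) -> float:
    total, count = 0.0, 0
    with nn.no_grad():
        for i in range(0, len(xv), batch_size):
            xb, yb = xv[i : i + batch_size], yv[i : i + batch_size]
            loss = content_loss(model.forward(xb), nn.Tensor(yb), loss_cfg)
            total += loss.item() * len(xb)
            count += len(xb)
    return total / count


def _check_finite(loss, epoch, batch):
    v = loss.item()
    if not math.isfinite(v):
        raise FloatingPointError(
            f"non-finite training loss at epoch {epoch}, batch {batch}: {v}"
        )
    return v


def finetune(model: SRModel, train_set, val_set, cfg: TrainConfig,
             loss_cfg: LossConfig | None = None,
             log=None) -> tuple[SRModel, TrainState]:
    """Fine-tune an SR model with the content loss; returns the model at
    the minimum-validation-L_c snapshot plus the training history."""
    loss_cfg = loss_cfg or LossConfig()
    xt, yt = _as_arrays(train_set)
    xv, yv = _as_arrays(val_set)
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("training and validation splits must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.module.parameters(), lr=cfg.lr0, betas=cfg.betas)
    state = TrainState()
    for epoch in range(cfg.epochs):
        lr = scheduled_lr(epoch, cfg.lr0, cfg.t0, cfg.t_mult, cfg.lr_floor)
        opt.lr = lr
        state.lr_trace.append(lr)
        perm = rng.permutation(len(xt))
        epoch_loss, seen = 0.0, 0
        for bi, start in enumerate(range(0, len(xt), cfg.batch_size)):
            idx = perm[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = content_loss(model.forward(xt[idx]), nn.Tensor(yt[idx]), loss_cfg)
            v = _check_finite(loss, epoch, bi)
            loss.backward()
            opt.step()
            epoch_loss += v * len(idx)
            seen += len(idx)
        state.train_loss.append(epoch_loss / seen)
        vl = _validation_loss(model, xv, yv, loss_cfg, cfg.batch_size)
        state.val_loss.append(vl)
        if vl < state.best_val_loss:
            state.best_val_loss = vl
            state.best_epoch = epoch
            state.best_state = copy.deepcopy(model.module.state_dict())
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.3e}  train Lc {state.train_loss[-1]:.5f}"
                f"  val Lc {vl:.5f}")
    model.module.load_state_dict(state.best_state)
    return model, state


def finetune_gan(generator: SRModel, discriminator: SRModel, train_set,
                 val_set, cfg: TrainConfig,
                 loss_cfg: LossConfig | None = None,
                 log=None) -> tuple[SRModel, TrainState]:
    """GAN fine-tuning: alternating per-batch discriminator/generator steps.

    Generator objective is L_c + lambda * L_GAN; validation and model
    selection use L_c only.  With lambda = 0 the discriminator is left
    untouched and the generator trajectory equals plain :func:`finetune`.
    """
    loss_cfg = loss_cfg or LossConfig(lambda_adv=0.05)
    lam = loss_cfg.lambda_adv
    if lam == 0:
        return finetune(generator, train_set, val_set, cfg, loss_cfg, log=log)

    xt, yt = _as_arrays(train_set)
    xv, yv = _as_arrays(val_set)
    if len(xt) == 0 or len(xv) == 0:
        raise ValueError("training and validation splits must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    g_opt = nn.Adam(generator.module.parameters(), lr=cfg.lr0, betas=cfg.betas)
    d_opt = nn.Adam(discriminator.module.parameters(), lr=cfg.disc_lr0,
                    betas=cfg.betas)
    state = TrainState()
    state.disc_loss = []
    for epoch in range(cfg.epochs):
        g_opt.lr = scheduled_lr(epoch, cfg.lr0, cfg.t0, cfg.t_mult, cfg.lr_floor)
        d_opt.lr = scheduled_lr(epoch, cfg.disc_lr0, cfg.disc_t0,
                                cfg.disc_t_mult, cfg.lr_floor)
        state.lr_trace.append(g_opt.lr)
        perm = rng.permutation(len(xt))
        g_epoch, d_epoch, seen = 0.0, 0.0, 0
        for bi, start in enumerate(range(0, len(xt), cfg.batch_size)):
            idx = perm[start : start + cfg.batch_size]
            yb = nn.Tensor(yt[idx])
            # discriminator step on detached generator output
            with nn.no_grad():
                fake_const = generator.forward(xt[idx]).data
            d_opt.zero_grad()
            _, d_loss = gan_losses(discriminator.forward(yt[idx]),
                                   discriminator.forward(fake_const))
            dv = _check_finite(d_loss, epoch, bi)
            d_loss.backward()
            d_opt.step()
            # generator step through the updated discriminator
            g_opt.zero_grad()
            fake = generator.forward(xt[idx])
            adv = nn.bce_with_logits_mean(discriminator.forward(fake), 1.0)
            g_loss = content_loss(fake, yb, loss_cfg) + lam * adv
            gv = _check_finite(g_loss, epoch, bi)
            g_loss.backward()
            # only the generator is updated here; discard discriminator grads
            discriminator.module.zero_grad()
            g_opt.step()
            g_epoch += gv * len(idx)
            d_epoch += dv * len(idx)
            seen += len(idx)
        state.train_loss.append(g_epoch / seen)
        state.disc_loss.append(d_epoch / seen)
        vl = _validation_loss(generator, xv, yv, loss_cfg, cfg.batch_size)
        state.val_loss.append(vl)
        if vl < state.best_val_loss:
            state.best_val_loss = vl
            state.best_epoch = epoch
            state.best_state = copy.deepcopy(generator.module.state_dict())
        if log is not None:
            log(f"epoch {epoch:3d}  G {state.train_loss[-1]:.5f}"
                f"  D {state.disc_loss[-1]:.5f}  val Lc {vl:.5f}")
    generator.module.load_state_dict(state.best_state)
    return generator, state
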