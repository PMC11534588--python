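import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slicesr as S
from slicesr.losses import IdentityFeatureProvider


def id_loss():
    return S.LossConfig(stage_weights=(1.0,),
                        provider=IdentityFeatureProvider(1))


def toy_sets(rng, n_train=12, n_val=4, size=16):
    """Synthetic (input, target) arrays: targets are inputs sharpened a bit,
    so a residual network has something learnable."""
    x = rng.random((n_train + n_val, 3, size, size))
    y = np.clip(x + 0.1 * (x - 0.5), 0, 1)
    return (x[:n_train], y[:n_train]), (x[n_train:], y[n_train:])


def tiny_model(seed=0):
    return S.build_model(S.ModelConfig(arch="edsr", n_blocks=1, n_features=4,
                                       scale=1), seed=seed)


# ------------------------------------------------------------ schedule --

def test_schedule_starts_at_lr0():
    assert S.scheduled_lr(0, 2e-4, 8, 2) == pytest.approx(2e-4)


def test_schedule_restarts_at_cumulative_cycle_sums():
    """T0=8, T_mult=2: cycles of 8, 16, 32 epochs restart at 8, 24, 56."""
    for e in (8, 24, 56):
        assert S.scheduled_lr(e, 2e-4, 8, 2) == pytest.approx(2e-4)
    for e in (7, 23, 55, 12):
        assert S.scheduled_lr(e, 2e-4, 8, 2) < 2e-4


def test_schedule_midpoint_half_amplitude():
    floor = 1e-7
    lr = S.scheduled_lr(4, 2e-4, 8, 1, floor)
    assert lr == pytest.approx(floor + (2e-4 - floor) / 2)


def test_schedule_closed_form_within_cycle():
    lr0, t0 = 1e-4, 6
    for e in range(6):
        expected = 1e-7 + (lr0 - 1e-7) * (1 + np.cos(np.pi * e / t0)) / 2
        assert S.scheduled_lr(e, lr0, t0, 1) == pytest.approx(expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 300))
def test_schedule_bounded(epoch):
    lr = S.scheduled_lr(epoch, 2e-4, 8, 2, 1e-7)
    assert 1e-7 <= lr <= 2e-4 + 1e-15


def test_schedule_invalid_parameters():
    with pytest.raises(ValueError):
        S.scheduled_lr(-1, 1e-4, 8, 2)
    with pytest.raises(ValueError):
        S.scheduled_lr(0, 1e-4, 0, 2)


# ------------------------------------------------------------ finetune --

def test_finetune_selects_min_validation_loss(rng):
    tr, va = toy_sets(rng)
    cfg = S.TrainConfig(epochs=4, batch_size=4, seed=0)
    _, state = S.finetune(tiny_model(), tr, va, cfg, id_loss())
    assert state.best_val_loss == pytest.approx(min(state.val_loss))
    assert state.val_loss[state.best_epoch] == state.best_val_loss


def test_finetune_deterministic(rng):
    tr, va = toy_sets(rng)
    cfg = S.TrainConfig(epochs=3, batch_size=4, seed=7)
    _, s1 = S.finetune(tiny_model(1), tr, va, cfg, id_loss())
    _, s2 = S.finetune(tiny_model(1), tr, va, cfg, id_loss())
    assert s1.train_loss == s2.train_loss
    assert s1.val_loss == s2.val_loss


def test_finetune_training_effect(rng):
    """A few epochs on learnable toy data reduce validation L_c below its
    initial value."""
    tr, va = toy_sets(rng, n_train=24)
    model = tiny_model(2)
    from slicesr.train import _validation_loss

    init = _validation_loss(model, va[0], va[1], id_loss(), 4)
    cfg = S.TrainConfig(epochs=6, batch_size=4, seed=0, lr0=1e-3)
    _, state = S.finetune(model, tr, va, cfg, id_loss())
    assert state.best_val_loss < init


def test_snapshot_does_not_alias_live_weights(rng):
    tr, va = toy_sets(rng)
    cfg = S.TrainConfig(epochs=2, batch_size=4, seed=0)
    model, state = S.finetune(tiny_model(), tr, va, cfg, id_loss())
    before = {k: v.copy() for k, v in state.best_state.items()}
    for p in model.module.parameters():
        p.data += 1.0
    for k in before:
        np.testing.assert_array_equal(state.best_state[k], before[k])


def test_lr_trace_bounded_and_restarts(rng):
    tr, va = toy_sets(rng, n_train=4, n_val=2)
    cfg = S.TrainConfig(epochs=10, batch_size=4, seed=0, t0=4, t_mult=1)
    _, state = S.finetune(tiny_model(), tr, va, cfg, id_loss())
    trace = np.array(state.lr_trace)
    assert np.all(trace >= cfg.lr_floor) and np.all(trace <= cfg.lr0 + 1e-15)
    assert trace[0] == pytest.approx(cfg.lr0)
    assert trace[4] == pytest.approx(cfg.lr0)
    assert trace[8] == pytest.approx(cfg.lr0)


def test_empty_split_errors(rng):
    tr, _ = toy_sets(rng)
    cfg = S.TrainConfig(epochs=1)
    with pytest.raises(ValueError, match="nonempty"):
        S.finetune(tiny_model(), tr, (np.zeros((0, 3, 16, 16)),) * 2, cfg,
                   id_loss())


# ------------------------------------------------------------- GAN -----

def disc_model(seed=0):
    return S.build_model(S.ModelConfig(arch="unet_discriminator",
                                       n_features=4), seed=seed)


def test_gan_lambda_zero_equals_plain_finetune(rng):
    tr, va = toy_sets(rng)
    cfg = S.TrainConfig(epochs=2, batch_size=4, seed=3)
    loss0 = S.LossConfig(lambda_adv=0.0, stage_weights=(1.0,),
                         provider=IdentityFeatureProvider(1))
    _, s_plain = S.finetune(tiny_model(5), tr, va, cfg, loss0)
    _, s_gan = S.finetune_gan(tiny_model(5), disc_model(), tr, va, cfg, loss0)
    assert s_plain.train_loss == s_gan.train_loss
    assert s_plain.val_loss == s_gan.val_loss


def test_gan_training_sane(rng):
    tr, va = toy_sets(rng, n_train=8, n_val=4)
    cfg = S.TrainConfig(epochs=3, batch_size=4, seed=0, disc_lr0=1e-3)
    loss = S.LossConfig(lambda_adv=0.05, stage_weights=(1.0,),
                        provider=IdentityFeatureProvider(1))
    gen, state = S.finetune_gan(tiny_model(1), disc_model(2), tr, va, cfg, loss)
    assert np.all(np.isfinite(state.disc_loss))
    assert state.disc_loss[-1] < state.disc_loss[0]
    # selection contract: best loss is the minimum of validation L_c
    assert state.best_val_loss == pytest.approx(min(state.val_loss))
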