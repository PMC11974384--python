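import math

import numpy as np
import pytest

import vemseg as v
from vemseg.training import (
    AugmentConfig,
    LossConfig,
    TrainConfig,
    augment,
    bce_loss,
    dicece_loss,
    dicece_loss_grad,
    sigmoid,
    soft_dice_loss,
)

# ---------------------------------------------------------------------------
# loss oracles


def test_dice_perfect_prediction_near_zero():
    g = np.array([1.0, 0.0, 1.0, 1.0])
    assert soft_dice_loss(g, g) < 1e-6


def test_dice_total_miss_near_one():
    g = np.array([1.0, 1.0, 0.0, 0.0])
    assert soft_dice_loss(1 - g, g) > 1 - 1e-6


def test_dice_half_confidence_hand_case():
    # g=[1,1,0,0], p=0.5 everywhere: dice = 2*1/(2+2) = 0.5 -> loss 0.5
    g = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.full(4, 0.5)
    assert abs(soft_dice_loss(p, g, smooth_eps=1e-12) - 0.5) < 1e-9


def test_bce_uniform_half_is_ln2():
    p = np.full(8, 0.5)
    g = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    assert abs(bce_loss(p, g) - math.log(2)) < 1e-12


def test_bce_matches_elementwise_oracle(rng):
    p = rng.uniform(0.05, 0.95, size=8)
    g = (rng.random(8) > 0.5).astype(float)
    oracle = -sum(
        gi * math.log(pi) + (1 - gi) * math.log(1 - pi) for pi, gi in zip(p, g)
    ) / len(p)
    assert abs(bce_loss(p, g) - oracle) < 1e-10


def test_dicece_degenerate_weights_reduce_to_components(rng):
    p = rng.uniform(0.1, 0.9, size=16)
    g = (rng.random(16) > 0.5).astype(float)
    assert dicece_loss(p, g, LossConfig(dice_weight=1, ce_weight=0)) == pytest.approx(
        soft_dice_loss(p, g), abs=1e-12
    )
    assert dicece_loss(p, g, LossConfig(dice_weight=0, ce_weight=1)) == pytest.approx(
        bce_loss(p, g), abs=1e-12
    )


def test_dicece_hand_case_half_plus_ln2():
    g = np.array([1.0, 1.0, 0.0, 0.0])
    p = np.full(4, 0.5)
    got = dicece_loss(p, g, LossConfig(smooth_eps=1e-12))
    assert abs(got - (0.5 + math.log(2))) < 1e-9


def test_loss_shape_mismatch_raises():
    with pytest.raises(ValueError, match="mismatch"):
        soft_dice_loss(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError, match="mismatch"):
        dicece_loss_grad(np.zeros((2, 2)), np.zeros((2, 3)))


def test_dicece_nonnegative_and_zero_only_at_perfect(rng):
    for _ in range(20):
        p = rng.random(12)
        g = (rng.random(12) > 0.5).astype(float)
        assert dicece_loss(p, g) >= 0
    g = (rng.random(12) > 0.5).astype(float)
    assert dicece_loss(g, g) < 1e-5


def test_loss_gradient_matches_finite_differences(rng):
    z = rng.normal(size=(2, 3, 3))
    g = (rng.random((2, 3, 3)) > 0.6).astype(float)
    cfg = LossConfig(dice_weight=0.7, ce_weight=1.3)
    loss, dz = dicece_loss_grad(z, g, cfg)
    assert loss == pytest.approx(dicece_loss(sigmoid(z), g, cfg), abs=1e-9)
    eps = 1e-6
    for _ in range(6):
        idx = tuple(rng.integers(0, s) for s in z.shape)
        zp = z.copy()
        zp[idx] += eps
        lp = dicece_loss(sigmoid(zp), g, cfg)
        zp[idx] -= 2 * eps
        lm = dicece_loss(sigmoid(zp), g, cfg)
        fd = (lp - lm) / (2 * eps)
        assert abs(fd - dz[idx]) < 1e-7 + 1e-5 * abs(fd)


# ---------------------------------------------------------------------------
# augmentation


def test_augment_disabled_is_identity(rng):
    img = rng.normal(size=(4, 8, 8))
    lab = (rng.random((4, 8, 8)) > 0.5).astype(np.float32)
    out_img, out_lab = augment(img, lab, AugmentConfig.none(), rng)
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_lab, lab)


def test_flip_is_involution():
    img = np.arange(8.0).reshape(2, 2, 2)
    once = np.flip(img, 2)
    np.testing.assert_array_equal(np.flip(once, 2), img)


def test_rot90_four_times_is_identity(rng):
    img = rng.normal(size=(2, 6, 6))
    out = img
    for _ in range(4):
        out = np.rot90(out, 1, axes=(1, 2))
    np.testing.assert_array_equal(out, img)


def test_geometric_augmentations_commute_with_loss(rng):
    """Flips/rotations applied to both prediction and target leave the
    DiceCE loss unchanged."""
    p = rng.random((4, 8, 8))
    g = (rng.random((4, 8, 8)) > 0.7).astype(float)
    base = dicece_loss(p, g)
    cfg = AugmentConfig(brightness_delta_range=(0.0, 0.0), contrast_scale_range=(1.0, 1.0))
    for seed in range(5):
        ap, ag = augment(p, g, cfg, np.random.default_rng(seed))
        assert dicece_loss(ap, ag) == pytest.approx(base, abs=1e-12)


def test_photometric_ops_touch_image_only(rng):
    img = rng.normal(size=(2, 4, 4))
    lab = (rng.random((2, 4, 4)) > 0.5).astype(np.uint8)
    cfg = AugmentConfig(flip_x=False, flip_y=False, flip_z=False, rot90_xy=False,
                        brightness_delta_range=(0.2, 0.2), contrast_scale_range=(1.5, 1.5))
    out_img, out_lab = augment(img.astype(float), lab.astype(float), cfg, rng)
    np.testing.assert_array_equal(out_lab, lab)
    assert set(np.unique(out_lab)) <= {0.0, 1.0}
    assert not np.allclose(out_img, img)


# ---------------------------------------------------------------------------
# training loop


def test_zero_epochs_returns_input_weights(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    ws = v.build_network(tiny_spec, seed=0)
    rec = v.train(ws, patches, labels, TrainConfig(max_epochs=0, seed=0))
    assert rec.epochs_run == 0
    for k in ws.params:
        np.testing.assert_array_equal(rec.weights.params[k], ws.params[k])


def test_training_is_deterministic(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    cfg = TrainConfig(max_epochs=2, batch_size=4, seed=11)
    a = v.train(v.build_network(tiny_spec, seed=3), patches, labels, cfg)
    b = v.train(v.build_network(tiny_spec, seed=3), patches, labels, cfg)
    assert a.train_loss == b.train_loss
    assert a.val_loss == b.val_loss
    for k in a.weights.params:
        np.testing.assert_array_equal(a.weights.params[k], b.weights.params[k])


def test_toy_task_loss_decreases(tiny_spec, tiny_task):
    """A separable bright-blob task: training loss trends down from the start."""
    patches, labels, *_ = tiny_task
    cfg = TrainConfig(max_epochs=5, batch_size=4, val_fraction=0.0, seed=0,
                      augmentations=AugmentConfig.none())
    rec = v.train(v.build_network(tiny_spec, seed=0), patches, labels, cfg)
    assert rec.epochs_run == 5
    assert all(b < a for a, b in zip(rec.train_loss, rec.train_loss[1:]))


def test_record_series_lengths_match_epochs(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    rec = v.train(v.build_network(tiny_spec, seed=0), patches, labels,
                  TrainConfig(max_epochs=2, seed=0))
    assert len(rec.train_loss) == len(rec.val_loss) == len(rec.val_iou) == rec.epochs_run


def test_empty_patch_set_rejected(tiny_spec):
    with pytest.raises(ValueError, match="empty"):
        v.train(v.build_network(tiny_spec, seed=0), [], [], TrainConfig(max_epochs=1))


# ---------------------------------------------------------------------------
# fine-tuning


def test_finetune_fraction_one_from_random_init_equals_train(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    cfg = TrainConfig(max_epochs=2, seed=4)
    ws = v.build_network(tiny_spec, seed=4)
    a = v.train(ws, patches, labels, cfg)
    b = v.fine_tune(ws, patches, labels, 1.0, cfg, seed=4)
    assert a.train_loss == b.train_loss
    for k in a.weights.params:
        np.testing.assert_array_equal(a.weights.params[k], b.weights.params[k])


def test_finetune_uses_rounded_fraction_of_patches():
    from vemseg.preprocess import subsample_fraction

    assert len(subsample_fraction(list(range(120)), 0.10, seed=0)) == 12


def test_finetune_rejects_bad_fraction(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    with pytest.raises(ValueError, match="fraction"):
        v.fine_tune(v.build_network(tiny_spec, seed=0), patches, labels, 0.0)


def test_finetune_sets_provenance(tiny_spec, tiny_task):
    patches, labels, *_ = tiny_task
    ws = v.build_network(tiny_spec, seed=0)
    rec = v.fine_tune(ws, patches, labels, 0.5, TrainConfig(max_epochs=1, seed=0), task_id="liver-M")
    assert rec.weights.provenance == "fine-tuned:liver-M"
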