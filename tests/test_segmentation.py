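"""Segmentation stack: VOI preprocessing, U-Net, losses, training, metrics."""

import numpy as np
import pytest

import bladderrad.seg.layers as layers_mod
import bladderrad.seg.unet as unet_mod
from bladderrad.phantom import generate_cohort
from bladderrad.seg import (
    SegNetConfig, TrainConfig, assign_vois, build_unet, combined_loss,
    cosine_lr, crop_from_pad, evaluate_cohort, focal_loss, minmax_normalize,
    pad_to_size, predict_lesion, seg_metrics, soft_dice_loss, train_segmenter,
    voi_from_mask,
)
from conftest import random_blob_mask


class TestVOI:
    def test_single_voxel_with_margin(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[5, 5, 5] = True
        v = voi_from_mask(mask, margin_vox=(2, 2, 2), jitter=0)
        assert (v.zmin, v.zmax, v.ymin, v.ymax, v.xmin, v.xmax) == (3, 8, 3, 8, 3, 8)

    def test_zero_margin_is_tight_bbox(self, rng):
        mask = random_blob_mask(rng)
        v = voi_from_mask(mask, margin_vox=(0, 0, 0), jitter=0)
        idx = np.argwhere(mask)
        assert (v.zmin, v.ymin, v.xmin) == tuple(idx.min(axis=0))
        assert (v.zmax, v.ymax, v.xmax) == tuple(idx.max(axis=0) + 1)

    def test_containment_under_jitter(self, rng):
        for _ in range(100):
            mask = random_blob_mask(rng)
            v = voi_from_mask(mask, margin_vox=(1, 2, 2), jitter=3, rng=rng)
            assert v.contains_mask(mask)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            voi_from_mask(np.zeros((4, 4, 4), bool))


class TestNormalizePad:
    def test_minmax_example(self):
        out = minmax_normalize(np.array([2.0, 4.0, 6.0]))
        assert np.allclose(out, [0, 0.5, 1])

    def test_constant_maps_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = minmax_normalize(np.full((3, 3), 5.0))
        assert np.all(out == 0) and "constant" in caplog.text

    def test_idempotent(self, rng):
        x = rng.normal(size=(6, 6))
        once = minmax_normalize(x)
        assert np.allclose(minmax_normalize(once), once)

    def test_pad_centering_convention(self):
        s = np.arange(15, dtype=float).reshape(3, 5)
        out = pad_to_size(s, 8)
        assert np.array_equal(out[2:5, 1:6], s)
        assert out.sum() == s.sum()

    @pytest.mark.parametrize("trial", range(50))
    def test_pad_crop_roundtrip(self, trial):
        rng = np.random.default_rng(trial)
        h, w = rng.integers(1, 17, size=2)
        s = rng.normal(size=(h, w))
        assert np.array_equal(crop_from_pad(pad_to_size(s, 16), (h, w)), s)

    def test_full_size_input_unchanged(self, rng):
        s = rng.normal(size=(8, 8))
        assert np.array_equal(pad_to_size(s, 8), s)

    def test_oversize_slice_rejected(self):
        with pytest.raises(ValueError):
            pad_to_size(np.zeros((9, 4)), 8)


class TestArchitecture:
    def test_bottleneck_arithmetic(self):
        assert SegNetConfig(256, 4, 8).bottleneck_side == 16
        assert SegNetConfig(64, 4, 8).bottleneck_side == 4

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError):
            SegNetConfig(100, 4, 8)

    @pytest.mark.parametrize("n", [32, 64])
    def test_output_shape_and_range(self, n):
        net = build_unet(SegNetConfig(n, 4, 2), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 1, n, n)).astype(np.float32)
        out = net.forward(x, train=False)
        assert out.shape == x.shape
        assert out.min() > 0 and out.max() < 1
        assert net.bottleneck_shape == (n // 16, n // 16)

    def test_end_to_end_gradients_match_numerics(self, monkeypatch):
        monkeypatch.setattr(layers_mod, "F", np.float64)
        monkeypatch.setattr(unet_mod, "F", np.float64)
        rng = np.random.default_rng(0)
        net = build_unet(SegNetConfig(16, 2, 2), seed=1)
        x = rng.normal(size=(2, 1, 16, 16))
        y = (rng.random((2, 1, 16, 16)) < 0.3).astype(float)
        prob = net.forward(x)
        _, grad, _ = combined_loss(prob, y, with_grad=True)
        net.backward(grad)
        checks = [net.enc[0].layers[0], net.enc[2].layers[3], net.ups[0],
                  net.dec[1].layers[1], net.head.layers[0]]
        eps = 1e-6
        for layer in checks:
            p = layer.params[0]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            ana = float(layer.grads[0][idx])
            w0 = float(p[idx])
            p[idx] = w0 + eps
            lp = combined_loss(net.forward(x), y)
            p[idx] = w0 - eps
            lm = combined_loss(net.forward(x), y)
            p[idx] = w0
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(ana, rel=1e-4, abs=1e-9)


class TestLosses:
    def test_focal_reduces_to_half_bce(self, rng):
        for _ in range(100):
            p = rng.uniform(0.01, 0.99, size=(40,))
            y = (rng.random(40) < 0.5).astype(float)
            bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            assert focal_loss(p, y, gamma=0.0, alpha=0.5) == pytest.approx(
                0.5 * bce, abs=1e-10)

    def test_focal_hand_evaluated_single_voxel(self):
        expected = 0.25 * 0.7**2 * (-np.log(0.3))
        assert focal_loss(np.array([0.3]), np.array([1.0]), 2.0, 0.25) == \
            pytest.approx(expected, rel=1e-6)

    def test_focal_vanishes_for_perfect_prediction(self):
        y = np.array([1.0, 0.0])
        losses = [focal_loss(np.array([1 - e, e]), y) for e in (1e-2, 1e-4, 1e-6)]
        assert losses == sorted(losses, reverse=True)
        assert losses[-1] < 1e-4

    def test_dice_zero_at_perfect_binary(self, rng):
        y = (rng.random((5, 5)) < 0.4).astype(float)
        assert soft_dice_loss(y, y, smooth=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_dice_closed_form_for_zero_prediction(self):
        y = np.zeros(20)
        y[:7] = 1.0
        s = 1.0
        assert soft_dice_loss(np.zeros(20), y, s) == pytest.approx(1 - s / (7 + s))

    def test_dice_monotone_towards_target(self, rng):
        p = rng.uniform(size=(30,))
        y = (rng.random(30) < 0.5).astype(float)
        losses = [soft_dice_loss(p + t * (y - p), y) for t in np.linspace(0, 1, 11)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_combined_weight_limits(self, rng):
        p = rng.uniform(0.01, 0.99, size=(25,))
        y = (rng.random(25) < 0.5).astype(float)
        assert combined_loss(p, y, w_focal=1, w_dice=0) == pytest.approx(
            focal_loss(p, y), abs=1e-12)
        assert combined_loss(p, y, w_focal=0, w_dice=1) == pytest.approx(
            soft_dice_loss(p, y), abs=1e-12)

    def test_loss_gradients_match_numerics(self, rng):
        p = rng.uniform(0.05, 0.95, size=(12,))
        y = (rng.random(12) < 0.5).astype(float)
        _, g, _ = combined_loss(p, y, with_grad=True)
        eps = 1e-7
        for i in range(0, 12, 3):
            pp, pm = p.copy(), p.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (combined_loss(pp, y) - combined_loss(pm, y)) / (2 * eps)
            assert num == pytest.approx(g[i], rel=1e-5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            focal_loss(np.zeros(3), np.zeros(4))


class TestSegMetrics:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        r = seg_metrics(m, m)
        assert (r.dsc, r.recall, r.precision) == (1.0, 1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        r = seg_metrics(a, b)
        assert (r.dsc, r.recall, r.precision) == (0.0, 0.0, 0.0)

    def test_hand_counted_overlap(self):
        pred = np.zeros((1, 1, 10), bool)
        ref = np.zeros((1, 1, 10), bool)
        pred[0, 0, :6] = True   # 6 voxels
        ref[0, 0, 3:7] = True   # 4 voxels, overlap 3
        r = seg_metrics(pred, ref)
        assert r.dsc == pytest.approx(0.6)
        assert r.recall == pytest.approx(0.75)
        assert r.precision == pytest.approx(0.5)

    def test_dsc_symmetry_and_harmonic_identity(self, rng):
        for _ in range(20):
            a = rng.random((6, 6, 6)) < 0.4
            b = rng.random((6, 6, 6)) < 0.4
            if not (a.any() and b.any()):
                continue
            r1, r2 = seg_metrics(a, b), seg_metrics(b, a)
            assert r1.dsc == pytest.approx(r2.dsc)
            p, rec = r1.precision, r1.recall
            if p + rec > 0:
                assert r1.dsc == pytest.approx(2 * p * rec / (p + rec))

    def test_empty_reference(self):
        with pytest.raises(ValueError):
            seg_metrics(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))


class TestSchedule:
    def test_cosine_endpoints_and_shape(self):
        T = 100
        lrs = [cosine_lr(t, T, 1e-3, 1e-5) for t in range(T)]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[-1] == pytest.approx(1e-5, abs=1e-8)
        expected = [0.5 * (1e-3 + 1e-5) + 0.5 * (1e-3 - 1e-5)
                    * np.cos(np.pi * t / (T - 1)) for t in range(T)]
        assert np.allclose(lrs, expected)
        assert all(b <= a for a, b in zip(lrs, lrs[1:]))


@pytest.fixture(scope="module")
def small_training():
    """One tiny seeded training run shared by the training-behavior tests."""
    from conftest import make_small_phantom_params

    params = make_small_phantom_params()
    train = generate_cohort(4, 2, "train", params, seed=21)
    val = generate_cohort(2, 1, "internal", params, seed=22)
    vois = assign_vois(train + val, margin_vox=(1, 3, 3), jitter=1, seed=5)
    net_cfg = SegNetConfig(48, 4, 4)
    cfg = TrainConfig(epochs=3, seed=13)
    seg = train_segmenter(train, vois, net_cfg, cfg)
    return params, train, val, vois, net_cfg, cfg, seg


class TestTraining:
    def test_loss_decreases(self, small_training):
        *_, seg = small_training
        assert seg.loss_trace[-1] < seg.loss_trace[0]

    def test_lr_trace_follows_schedule(self, small_training):
        cfg, seg = small_training[5], small_training[6]
        assert seg.lr_trace[0] == pytest.approx(cfg.lr_start)
        assert seg.lr_trace[-1] == pytest.approx(cfg.lr_end, abs=1e-8)

    def test_training_is_bit_reproducible(self, small_training):
        params, train, val, vois, net_cfg, cfg, seg = small_training
        seg2 = train_segmenter(train, vois, net_cfg, cfg)
        assert seg.loss_trace == seg2.loss_trace
        d1 = evaluate_cohort(seg, val, vois)
        d2 = evaluate_cohort(seg2, val, vois)
        for lid in d1:
            assert d1[lid]["dsc"] == pytest.approx(d2[lid]["dsc"], abs=1e-5)

    def test_prediction_contract(self, small_training):
        params, train, val, vois, *_, seg = small_training
        pred = predict_lesion(seg, val[0], vois[val[0].id])
        assert pred.prob.min() >= 0 and pred.prob.max() <= 1
        outside = np.ones_like(pred.prob, dtype=bool)
        outside[pred.voi.slices] = False
        assert np.all(pred.prob[outside] == 0)
        assert np.array_equal(pred.mask, pred.mask & (pred.prob >= 0.5))

    def test_empty_training_set_rejected(self, small_training):
        *_, net_cfg, cfg, _ = small_training
        with pytest.raises(ValueError):
            train_segmenter([], {}, net_cfg, cfg)
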