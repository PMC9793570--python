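"""Network, loss, training loop and fold assignment."""

import numpy as np
import pytest

from hepavol import CTVolume, BinaryMask, ThresholdSegmenter, dice, threshold_segmenter
from hepavol.nn import DynUNetConfig, TrainConfig, build_model, combined_loss, \
    combined_loss_grad, load_checkpoint, make_folds, predict_mask, save_checkpoint, \
    sigmoid, train
from hepavol.nn.loss import cross_entropy_loss, soft_dice_loss


def loss_oracle(p, g, wd, wc, smooth):
    """Independent scalar computation of the combined loss."""
    p = np.asarray(p, float).ravel()
    g = np.asarray(g, float).ravel()
    inter = sum(pi * gi for pi, gi in zip(p, g))
    dice_term = 1.0 - (2 * inter + smooth) / (sum(p) + sum(g) + smooth)
    eps = 1e-7
    ce = -np.mean([gi * np.log(max(pi, eps)) + (1 - gi) * np.log(max(1 - pi, eps))
                   for pi, gi in zip(p, g)])
    return wd * dice_term + wc * ce


class TestCombinedLoss:
    def test_perfect_binary_dice_zero(self):
        g = (np.random.default_rng(0).random((4, 4, 4)) > 0.5)
        assert combined_loss(g.astype(float), g, 1.0, 0.0, smooth=0.0) == 0.0

    def test_uniform_half_cross_entropy_is_ln2(self):
        g = (np.random.default_rng(1).random((4, 4, 4)) > 0.5)
        loss = combined_loss(np.full((4, 4, 4), 0.5), g, 0.0, 1.0)
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_hand_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.random((4, 4, 4))
            g = rng.random((4, 4, 4)) > 0.5
            expected = loss_oracle(p, g, 0.5, 0.5, 1e-5)
            assert combined_loss(p, g, 0.5, 0.5) == pytest.approx(expected, abs=1e-9)

    def test_soft_dice_symmetric_for_binary_masks(self):
        rng = np.random.default_rng(3)
        p = (rng.random((4, 4, 4)) > 0.5).astype(float)
        g = (rng.random((4, 4, 4)) > 0.5).astype(float)
        assert soft_dice_loss(p, g) == pytest.approx(soft_dice_loss(g, p), abs=1e-12)

    def test_shape_mismatch_and_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            combined_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)), 0.0, 0.0)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(3, 3, 3)).astype(np.float64)
        g = (rng.random((3, 3, 3)) > 0.5).astype(np.float64)
        _, dz = combined_loss_grad(z, g, 0.7, 0.3)
        eps = 1e-5
        for idx in [(0, 0, 0), (1, 2, 0), (2, 2, 2)]:
            zp = z.copy(); zp[idx] += eps
            zm = z.copy(); zm[idx] -= eps
            lp, _ = combined_loss_grad(zp, g, 0.7, 0.3)
            lm, _ = combined_loss_grad(zm, g, 0.7, 0.3)
            num = (lp - lm) / (2 * eps)
            # dz is emitted as float32; tolerance reflects that precision
            assert dz[idx] == pytest.approx(num, abs=1e-4)


class TestModel:
    def test_output_shape_matches_input(self):
        cfg = DynUNetConfig(n_levels=3, initial_features=4, patch_shape=(16, 16, 16))
        model = build_model(cfg)
        x = np.zeros((1, 1, 16, 16, 16), np.float32)
        assert model.forward(x).shape == (1, 1, 16, 16, 16)
        outs = model.forward(x, train=True)
        assert [o.shape[2] for o in outs] == [16, 8, 4]

    def test_same_seed_identical_parameters(self):
        cfg = DynUNetConfig(seed=9, patch_shape=(16, 16, 16))
        a, b = build_model(cfg), build_model(cfg)
        assert all(np.array_equal(pa.value, pb.value)
                   for pa, pb in zip(a.params(), b.params()))

    def test_feature_doubling_rule(self):
        cfg = DynUNetConfig(n_levels=3, initial_features=8, patch_shape=(16, 16, 16))
        assert cfg.feature_counts == [8, 16, 32]
        model = build_model(cfg)
        # first conv of each encoder level carries the doubled channel count
        for level, blocks in enumerate(model.enc_levels):
            assert blocks[0].conv1.w.value.shape[0] == 8 * 2**level

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            DynUNetConfig(n_levels=4, patch_shape=(20, 20, 20))

    def test_model_gradients_match_finite_differences(self):
        """Whole-network gradient check on a tiny configuration."""
        cfg = DynUNetConfig(n_levels=2, initial_features=2, res_blocks_per_level=1,
                            deep_supervision_heads=1, patch_shape=(4, 4, 4), seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32)
        y = (rng.random((1, 1, 4, 4, 4)) > 0.5).astype(np.float32)
        weights = [2 / 3, 1 / 3]

        def total_loss():
            tot = 0.0
            for i, lg in enumerate(model.forward(x, train=True)):
                t = y[:, :, :: 2**i, :: 2**i, :: 2**i]
                l, _ = combined_loss_grad(lg, t, 1.0, 1.0)
                tot += weights[i] * l
            return tot

        outs = model.forward(x, train=True)
        model.zero_grad()
        dl = []
        for i, lg in enumerate(outs):
            t = y[:, :, :: 2**i, :: 2**i, :: 2**i]
            _, dz = combined_loss_grad(lg, t, 1.0, 1.0)
            dl.append(weights[i] * dz)
        model.backward(dl)

        eps = 1e-3
        rngp = np.random.default_rng(7)
        for p in model.params():
            flat = p.value.ravel()
            for idx in rngp.choice(flat.size, size=min(2, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + eps
                lp = total_loss()
                flat[idx] = old - eps
                lm = total_loss()
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[idx]
                assert ana == pytest.approx(num, abs=1e-2 * max(1.0, abs(num)))

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = DynUNetConfig(n_levels=2, initial_features=2, patch_shape=(8, 8, 8),
                            deep_supervision_heads=0, seed=2)
        model = build_model(cfg)
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        path = tmp_path / "ck.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.allclose(model.forward(x), back.forward(x))


class TestTrain:
    def _tiny_setup(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(100, 10, (8, 8, 8)).astype(np.float32)
        vals[2:6, 2:6, 2:6] += 100
        vol = CTVolume(vals, (1, 1, 1))
        mask = BinaryMask(vals > 150, (1, 1, 1))
        cfg = DynUNetConfig(n_levels=2, initial_features=2, res_blocks_per_level=1,
                            deep_supervision_heads=1, patch_shape=(8, 8, 8), seed=1)
        return build_model(cfg), [(vol, mask)]

    def test_zero_epochs_returns_unchanged(self):
        model, cases = self._tiny_setup()
        before = [p.value.copy() for p in model.params()]
        model, hist = train(model, cases, TrainConfig(epochs=0))
        assert hist == []
        assert all(np.array_equal(b, p.value)
                   for b, p in zip(before, model.params()))

    def test_training_is_seed_deterministic(self):
        tc = TrainConfig(epochs=2, steps_per_epoch=3, batch_size=1, seed=4)
        m1, cases = self._tiny_setup()
        m1, h1 = train(m1, cases, tc)
        m2, _ = self._tiny_setup()[0], None
        m2, cases2 = self._tiny_setup()
        m2, h2 = train(m2, cases2, tc)
        assert h1 == h2
        assert all(np.array_equal(a.value, b.value)
                   for a, b in zip(m1.params(), m2.params()))

    def test_empty_dataset_rejected(self):
        model, _ = self._tiny_setup()
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())


class TestPredictMask:
    def test_deterministic_and_padding(self):
        cfg = DynUNetConfig(n_levels=2, initial_features=2, res_blocks_per_level=1,
                            deep_supervision_heads=0, patch_shape=(8, 8, 8), seed=6)
        model = build_model(cfg)
        vol = CTVolume(np.random.default_rng(1).normal(100, 20, (6, 11, 9)), (1, 1, 1))
        m1 = predict_mask(model, vol)
        m2 = predict_mask(model, vol)
        assert np.array_equal(m1.values, m2.values)
        assert m1.shape == vol.shape

    def test_all_background_prediction_is_empty(self):
        cfg = DynUNetConfig(n_levels=2, initial_features=2, res_blocks_per_level=1,
                            deep_supervision_heads=0, patch_shape=(8, 8, 8), seed=6)
        model = build_model(cfg)
        model.head.b.value[...] = -20.0  # force background logits
        vol = CTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        assert predict_mask(model, vol).is_empty()

    def test_bad_threshold_rejected(self):
        cfg = DynUNetConfig(n_levels=2, initial_features=2,
                            deep_supervision_heads=0, patch_shape=(8, 8, 8))
        model = build_model(cfg)
        vol = CTVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError):
            predict_mask(model, vol, threshold=1.5)


class TestThresholdSegmenter:
    def test_band_extremes(self, small_phantom):
        ct, _ = small_phantom
        full = threshold_segmenter(ct, ct.values.min() - 1, ct.values.max() + 1)
        assert full.count() == np.prod(ct.shape)
        empty = threshold_segmenter(ct, 1e6, 2e6)
        assert empty.is_empty()

    def test_recovers_liver_on_noise_free_phantom(self, small_phantom):
        """A band at parenchyma level recovers the liver almost exactly."""
        ct, truth = small_phantom
        mask = threshold_segmenter(ct, 45.0, 400.0)
        assert dice(mask, truth.liver_mask) >= 99.0

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSegmenter(10.0, 5.0)


class TestMakeFolds:
    def test_balanced_118_case_split(self):
        ids = [f"p{i:03d}" for i in range(118)]
        folds = make_folds(ids, 5, seed=0)
        assert sorted(folds.fold_sizes(), reverse=True) == [24, 24, 24, 23, 23]

    def test_partition_property(self):
        ids = [f"p{i}" for i in range(10)]
        folds = make_folds(ids, 5, seed=1)
        assert folds.fold_sizes() == [2, 2, 2, 2, 2]
        all_members = [c for f in range(5) for c in folds.fold_members(f)]
        assert sorted(all_members) == sorted(ids)  # each id exactly once

    def test_seed_reproducible(self):
        ids = [f"p{i}" for i in range(30)]
        assert make_folds(ids, 5, seed=3).assignment == make_folds(ids, 5, seed=3).assignment
        assert make_folds(ids, 5, seed=3).assignment != make_folds(ids, 5, seed=4).assignment

    def test_duplicates_and_bad_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "a", "b"], 2)
        with pytest.raises(ValueError):
            make_folds(["a", "b", "c"], 5)


def test_sigmoid_stable_at_extremes():
    z = np.array([-500.0, 0.0, 500.0], np.float32)
    s = sigmoid(z)
    assert np.all(np.isfinite(s))
    assert s[1] == pytest.approx(0.5)
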