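"""Patch-detector network: activations, attention gates, gradients, training."""

import numpy as np
import pytest

from ctforensics import nn
from ctforensics.detector import (DetectorConfig, DetectorModel, TrainConfig,
                                  build_detector, predict_patches, train_detector)

LAM, ALPHA = nn.SELU_LAMBDA, nn.SELU_ALPHA

TINY = dict(input_size=8, stem=(3, 4), stages=(4,), blocks_per_stage=2, dense=5)


class TestSelu:
    def test_canonical_values(self):
        assert nn.selu(0.0) == 0.0
        assert np.isclose(nn.selu(1.0), LAM)
        assert np.isclose(nn.selu(-20.0), -LAM * ALPHA, atol=1e-6)

    def test_continuous_and_strictly_increasing(self):
        x = np.linspace(-6, 6, 2001)
        y = nn.selu(x)
        assert np.all(np.diff(y) > 0)
        assert abs(nn.selu(1e-9) - nn.selu(-1e-9)) < 1e-6


class TestSpatialAttention:
    def test_zero_weights_give_uniform_half(self):
        rng = np.random.default_rng(0)
        sa = nn.SpatialAttention(rng, k=7)
        sa.conv.w.value[...] = 0.0
        sa.conv.b.value[...] = 0.0
        F = rng.normal(size=(2, 5, 8, 8))
        a, _ = sa.attention_map(F)
        np.testing.assert_allclose(a, 0.5)

    def test_hand_evaluated_single_pixel(self):
        # 1x1 kernel with weights (1, 1), bias 0; channel max 3 and mean 1
        rng = np.random.default_rng(0)
        sa = nn.SpatialAttention(rng, k=1)
        sa.conv.w.value[...] = 1.0
        sa.conv.b.value[...] = 0.0
        F = np.array([3.0, -1.0]).reshape(1, 2, 1, 1)  # max 3, mean 1
        a, _ = sa.attention_map(F)
        assert np.isclose(a.item(), 1 / (1 + np.exp(-4.0)), atol=1e-5)
        assert np.isclose(a.item(), 0.98201, atol=1e-5)

    def test_output_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        sa = nn.SpatialAttention(rng, k=7)
        F = rng.normal(size=(3, 6, 16, 16)) * 5
        a, _ = sa.attention_map(F)
        assert np.all(a > 0) and np.all(a < 1)


class TestChannelAttention:
    def test_zero_weights_give_half_per_channel(self):
        rng = np.random.default_rng(0)
        ca = nn.ChannelAttention(8, rng)
        for p in ca.params():
            p.value[...] = 0.0
        F = rng.normal(size=(2, 8, 4, 4))
        a, _ = ca.attention_vector(F)
        np.testing.assert_allclose(a, 0.5)

    def test_constant_feature_collapses_max_and_avg_paths(self):
        rng = np.random.default_rng(2)
        ca = nn.ChannelAttention(4, rng)
        const = rng.normal(size=(3, 4))
        F = np.broadcast_to(const[:, :, None, None], (3, 4, 6, 6)).copy()
        a, _ = ca.attention_vector(F)
        z, _ = ca.mlp.forward(const.astype(nn.DTYPE))
        np.testing.assert_allclose(a, nn.sigmoid(2 * z), rtol=1e-5)

    def test_bottleneck_width_is_quarter_of_channels(self):
        ca = nn.ChannelAttention(8, np.random.default_rng(0))
        assert ca.mlp.hidden == 2
        assert nn.ChannelAttention(2, np.random.default_rng(0)).mlp.hidden == 1


class TestGradients:
    def test_full_model_matches_finite_differences(self, float64_engine):
        model = DetectorModel(DetectorConfig(**TINY), seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 1, 8, 8))
        y = np.array([0, 1, 1, 0, 1])

        def loss_fn():
            loss, _ = nn.softmax_cross_entropy(model.logits(x, train=True), y)
            return loss

        for p in model.params():
            p.grad[...] = 0.0
        loss, dl = nn.softmax_cross_entropy(model.logits(x, train=True), y)
        model.backward(dl)

        eps = 1e-6
        check_rng = np.random.default_rng(2)
        for p in model.params():
            flat = p.value.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_fn()
                flat[i] = orig - eps
                lm = loss_fn()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = p.grad.ravel()[i]
                assert abs(num - ana) <= 1e-5 + 1e-4 * (abs(num) + abs(ana)), (
                    f"gradient mismatch: numeric {num} vs analytic {ana}"
                )


class TestBuildDetector:
    def test_probability_contract_and_seed_determinism(self):
        m1 = build_detector(DetectorConfig(**TINY), seed=3)
        m2 = build_detector(DetectorConfig(**TINY), seed=3)
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a.value, b.value)
        p = m1.predict(np.random.default_rng(0).normal(size=(4, 8, 8)))
        assert np.all((p >= 0) & (p <= 1))
        m3 = build_detector(DetectorConfig(**TINY), seed=4)
        assert any(not np.array_equal(a.value, b.value)
                   for a, b in zip(m1.params(), m3.params()))

    def test_parameter_count_matches_arithmetic_oracle(self):
        """Count parameters layer-by-layer from the architecture definition."""
        cfg = DetectorConfig()
        expected = 0
        cin = 1
        for w in cfg.stem:               # 3x3 conv + BN
            expected += 9 * cin * w + 2 * w
            cin = w
        expected += 2 * 49 * 1 + 1       # spatial attention 7x7 conv on [max;mean], bias
        for w in cfg.stages:
            # transition: two sepconvs (dw 3x3 + pw 1x1) + 2 BN, 1x1 shortcut + BN
            expected += (9 * cin + cin * w + 2 * w) + (9 * w + w * w + 2 * w)
            expected += cin * w + 2 * w
            for _ in range(cfg.blocks_per_stage - 1):   # identity blocks
                expected += 2 * (9 * w + w * w + 2 * w)
            cin = w
        hidden = cin // 4                # channel attention shared MLP
        expected += cin * hidden + hidden + hidden * cin + cin
        expected += cin * cfg.dense + cfg.dense          # dense head
        expected += cfg.dense * 2 + 2                    # softmax logits
        model = build_detector(cfg, seed=0)
        assert model.n_params() == expected
        assert model.n_params() < 1_500_000

    def test_input_size_must_survive_poolings(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=8, stages=(4, 8, 16, 32))


class TestPredict:
    def test_batch_invariance_and_duplicates(self):
        model = build_detector(DetectorConfig(**TINY), seed=0)
        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 8, 8))
        batched = model.predict(X)
        single = np.array([model.predict(X[i : i + 1])[0] for i in range(7)])
        np.testing.assert_allclose(batched, single, atol=1e-6)
        dup = model.predict(np.stack([X[0], X[0]]))
        assert dup[0] == dup[1]

    def test_wrong_patch_shape_rejected(self):
        model = build_detector(DetectorConfig(**TINY), seed=0)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 16, 16)))


@pytest.fixture(scope="module")
def trained_tiny(request):
    """One small detector trained on separable disk-vs-noise patches."""
    rng = np.random.default_rng(0)
    size, n = 16, 100
    neg = rng.normal(0.3, 0.05, size=(n, size, size))
    pos = rng.normal(0.3, 0.05, size=(n, size, size))
    yy, xx = np.mgrid[:size, :size]
    pos += 0.4 * np.exp(-((yy - 8) ** 2 + (xx - 8) ** 2) / 12)[None]
    X = np.concatenate([neg, pos])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    cfg = DetectorConfig(input_size=16, stem=(4, 8), stages=(8, 16), dense=16)
    model = build_detector(cfg, seed=0)
    train_detector(model, X, y, X[::4], y[::4], TrainConfig(max_epochs=12, seed=0))
    return model, X, y


class TestTraining:
    def test_separable_patches_reach_high_accuracy(self, trained_tiny):
        model, X, y = trained_tiny
        acc = ((model.predict(X) > 0.5).astype(int) == y).mean()
        assert acc >= 0.99

    def test_early_stopping_on_flat_validation(self, trained_tiny):
        model, _, _ = trained_tiny
        # validation saturates quickly on separable data: the patience-3 rule
        # must halt training well before the epoch cap
        assert len(model.history) < 12

    def test_single_class_and_empty_validation_rejected(self):
        model = build_detector(DetectorConfig(**TINY), seed=0)
        X = np.zeros((4, 8, 8))
        with pytest.raises(ValueError):
            train_detector(model, X, [1, 1, 1, 1], X, [1, 0, 1, 0], TrainConfig(max_epochs=2))
        with pytest.raises(ValueError):
            train_detector(model, X, [1, 0, 1, 0], X[:0], [], TrainConfig(max_epochs=2))

    def test_training_deterministic_for_fixed_seed(self, disk_patches):
        X, y = disk_patches(n_per_class=20, size=8)
        losses = []
        for _ in range(2):
            model = build_detector(DetectorConfig(**TINY), seed=1)
            train_detector(model, X, y, X[::3], y[::3],
                           TrainConfig(max_epochs=4, seed=1))
            losses.append(model.history[-1]["loss"])
        assert losses[0] == losses[1]


class TestPersistence:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path, trained_tiny):
        model, X, _ = trained_tiny
        path = tmp_path / "det.npz"
        model.save(path)
        loaded = type(model).load(path)
        np.testing.assert_allclose(loaded.predict(X[:10]), model.predict(X[:10]),
                                   atol=1e-7)
        assert loaded.history == model.history


class TestAttentionAblation:
    def test_ablated_model_still_trains_and_full_is_no_worse(self, disk_patches):
        """Direction of the attention ablation, as a soft multi-seed property."""
        X, y = disk_patches(n_per_class=40, size=16, seed=3)
        Xv, yv = X[::3], y[::3]
        cfg_full = DetectorConfig(input_size=16, stem=(4, 8), stages=(8, 16), dense=16)
        cfg_abl = DetectorConfig(input_size=16, stem=(4, 8), stages=(8, 16), dense=16,
                                 spatial_attention=False, channel_attention=False)
        full_acc, abl_acc = [], []
        for seed in (0, 1, 2):
            for cfg, accs in ((cfg_full, full_acc), (cfg_abl, abl_acc)):
                m = build_detector(cfg, seed=seed)
                train_detector(m, X, y, Xv, yv, TrainConfig(max_epochs=6, seed=seed))
                accs.append(max(h["val_acc"] for h in m.history))
        assert np.mean(full_acc) >= np.mean(abl_acc) - 0.05
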