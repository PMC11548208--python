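"""Network architecture contracts, analytic gradients, dice loss, training."""

import numpy as np
import pytest

from headseg import ConfigurationError, ShapeError, UNetConfig, build_model, dice_loss
from headseg.train import TrainConfig, train_on_windows
from headseg.unet import dice_loss_grad, load_checkpoint, save_checkpoint

TINY = UNetConfig(in_channels=2, level_channels=(2, 3, 4, 5, 6), conv_kernel=3, conv_padding=1)


class TestConfig:
    def test_default_deepest_width_is_256(self):
        m = build_model(seed=0)
        assert m.enc[4][1].conv.w.data.shape[0] == 256
        assert m.cfg.bottleneck_channels == 512

    def test_length_breaking_padding_rejected(self):
        with pytest.raises(ConfigurationError):
            UNetConfig(conv_kernel=9, conv_padding=3)

    @pytest.mark.parametrize("bad", [
        dict(level_channels=(16, 32, 64, 128)),          # not five levels
        dict(level_channels=(16, 16, 64, 128, 256)),     # not strictly increasing
        dict(conv_stride=2),
        dict(out_channels=2),
        dict(upsample_mode="bilinear"),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            UNetConfig(**bad)


class TestForwardContract:
    def test_seeded_builds_bit_identical(self):
        a, b = build_model(TINY, seed=0), build_model(TINY, seed=0)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)
        c = build_model(TINY, seed=1)
        assert any(
            not np.array_equal(pa.data, pc.data)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    @pytest.mark.parametrize("length", [32, 64, 96, 320])
    def test_length_preserved_and_probabilistic(self, length, rng):
        m = build_model(TINY, seed=0)
        x = rng.normal(size=(2, 2, length))
        p = m(x)
        assert p.shape == (2, 1, length)
        assert np.all((p > 0) & (p < 1))

    def test_invalid_length_names_divisor(self):
        m = build_model(TINY, seed=0)
        with pytest.raises(ShapeError, match="32"):
            m(np.zeros((1, 2, 100)))

    def test_eval_mode_deterministic(self, rng):
        m = build_model(TINY, seed=0)
        x = rng.normal(size=(1, 2, 64))
        assert np.array_equal(m(x), m(x))

    @pytest.mark.parametrize("level", range(5))
    def test_every_skip_connection_contributes(self, level, rng):
        """Zeroing one encoder skip must change the output (no dropped concat)."""
        m = build_model(TINY, seed=0)
        x = rng.normal(size=(1, 2, 64))
        full = m.forward(x, training=False)
        ablated = m.forward(x, training=False, drop_skip=level)
        assert not np.allclose(full, ablated)


class TestGradients:
    """Backprop checked against central finite differences (the oracle)."""

    @pytest.mark.parametrize("mode", ["fixed_upsample", "transposed_conv"])
    def test_parameter_gradients_match_finite_differences(self, mode, rng):
        cfg = UNetConfig(
            in_channels=2, level_channels=(2, 3, 4, 5, 6),
            conv_kernel=3, conv_padding=1, upsample_mode=mode,
        )
        m = build_model(cfg, seed=0, dtype=np.float64)
        x = rng.normal(size=(2, 2, 32))
        y = (rng.random((2, 1, 32)) < 0.4).astype(np.float64)

        def loss_fn():
            return dice_loss_grad(m.forward(x, training=True), y)[0]

        _, g = dice_loss_grad(m.forward(x, training=True), y)
        m.backward(g)
        h = 1e-6
        check_rng = np.random.default_rng(0)
        for p in m.parameters():
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in check_rng.integers(0, flat.size, size=min(3, flat.size)):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_fn()
                flat[idx] = orig - h
                down = loss_fn()
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                assert gflat[idx] == pytest.approx(fd, rel=2e-4, abs=1e-7), p.name

    def test_input_gradient_matches_finite_differences(self, rng):
        m = build_model(TINY, seed=0, dtype=np.float64)
        x = rng.normal(size=(1, 2, 32))
        y = (rng.random((1, 1, 32)) < 0.4).astype(np.float64)
        _, g = dice_loss_grad(m.forward(x, training=True), y)
        dx = m.backward(g)
        h = 1e-6
        for idx in np.random.default_rng(1).integers(0, x.size, size=8):
            i = np.unravel_index(idx, x.shape)
            orig = x[i]
            x[i] = orig + h
            up = dice_loss_grad(m.forward(x, training=True), y)[0]
            x[i] = orig - h
            down = dice_loss_grad(m.forward(x, training=True), y)[0]
            x[i] = orig
            assert dx[i] == pytest.approx((up - down) / (2 * h), rel=2e-4, abs=1e-7)


class TestDiceLoss:
    def test_hand_computed_values(self):
        ones, zeros = np.ones(10), np.zeros(10)
        assert dice_loss(ones, ones, smooth=1e-6) == pytest.approx(0.0, abs=1e-6)
        assert dice_loss(ones, zeros, smooth=1e-6) == pytest.approx(1.0, abs=1e-6)
        # 1 - 2*1/(2+2) by the formula
        assert dice_loss([1, 1, 0, 0], [0, 1, 1, 0], smooth=0.0) == pytest.approx(0.5)

    def test_symmetry_for_binary_arguments(self, rng):
        for _ in range(20):
            p = (rng.random(50) < 0.5).astype(float)
            t = (rng.random(50) < 0.5).astype(float)
            assert dice_loss(p, t) == pytest.approx(dice_loss(t, p))

    def test_bounds_with_positive_smooth(self, rng):
        for _ in range(50):
            p = rng.random(40)
            t = (rng.random(40) < 0.5).astype(float)
            assert 0.0 <= dice_loss(p, t, smooth=1e-6) <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ShapeError):
            dice_loss(np.ones(3), np.ones(4))


class TestTraining:
    def _toy_windows(self, rng, n=2, length=64):
        y = np.zeros((n, 1, length), dtype=np.float32)
        x = rng.normal(0, 0.05, size=(n, 3, length)).astype(np.float32)
        for i in range(n):
            lo = 10 + 5 * i
            y[i, 0, lo:lo + 24] = 1
            x[i, 0, lo:lo + 24] += 3.0
        return x, y

    def test_loss_decreases_when_overfitting(self, rng):
        x, y = self._toy_windows(rng)
        m = build_model(seed=0)
        res = train_on_windows(m, x, y, TrainConfig(epochs=30, batch_size=2, seed=0))
        assert res.loss_history[-1] < res.loss_history[0]

    def test_training_is_seed_deterministic(self, rng):
        x, y = self._toy_windows(rng)
        histories = []
        for _ in range(2):
            m = build_model(seed=0)
            res = train_on_windows(m, x, y, TrainConfig(epochs=5, batch_size=1, seed=3))
            histories.append(res.loss_history)
        assert histories[0] == histories[1]

    def test_empty_training_set_raises(self):
        from headseg.errors import EmptyInputError

        m = build_model(TINY, seed=0)
        with pytest.raises(EmptyInputError):
            train_on_windows(m, np.zeros((0, 2, 32)), np.zeros((0, 1, 32)), TrainConfig(epochs=1))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, rng):
        m = build_model(TINY, seed=0)
        x = rng.normal(size=(1, 2, 64))
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(m, path)
        m2, meta = load_checkpoint(path)
        assert np.allclose(m(x), m2(x))
        assert m2.cfg == m.cfg

    def test_version_check(self, tmp_path):
        import json

        m = build_model(TINY, seed=0)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(m, path)
        data = dict(np.load(path))
        header = json.loads(bytes(data["header"]).decode())
        header["format_version"] = 999
        data["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ConfigurationError):
            load_checkpoint(path)
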