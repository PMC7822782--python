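"""4D convolution oracle checks, dense-block bookkeeping, gradients."""
import numpy as np
import pytest

from oce4d import ModelSpec, build_model, conv4d, load_checkpoint, save_checkpoint
from oce4d.errors import ConfigurationError, ShapeError
from oce4d.net4d import AvgPool4d, DenseBlock, GlobalAvgPool, Linear


def conv4d_reference(x: np.ndarray, w: np.ndarray, stride=1) -> np.ndarray:
    """Direct four-fold nested summation over zero-padded input (the oracle)."""
    st = (stride,) * 4 if np.isscalar(stride) else tuple(stride)
    kt, kx, ky, kz, cin, cout = w.shape
    pads = [(0, 0)] + [(k // 2, k // 2) for k in (kt, kx, ky, kz)] + [(0, 0)]
    xp = np.pad(x, pads)
    outs = [
        (x.shape[1 + i] + 2 * (k // 2) - k) // s + 1
        for i, (k, s) in enumerate(zip((kt, kx, ky, kz), st))
    ]
    y = np.zeros((x.shape[0], *outs, cout))
    for b in range(x.shape[0]):
        for t in range(outs[0]):
            for i in range(outs[1]):
                for j in range(outs[2]):
                    for m in range(outs[3]):
                        acc = np.zeros(cout)
                        for dt in range(kt):
                            for dx in range(kx):
                                for dy in range(ky):
                                    for dz in range(kz):
                                        acc += (
                                            xp[b, t * st[0] + dt, i * st[1] + dx,
                                               j * st[2] + dy, m * st[3] + dz]
                                            @ w[dt, dx, dy, dz]
                                        )
                        y[b, t, i, j, m] = acc
    return y


class TestConv4d:
    def test_identity_kernel(self, rng):
        w = np.zeros((3, 3, 3, 3, 1, 1))
        w[1, 1, 1, 1, 0, 0] = 1.0
        x = rng.normal(size=(4, 5, 5, 5, 1))
        assert np.allclose(conv4d(x, w), x, atol=1e-10)

    def test_all_ones_kernel_interior_sum(self):
        x = np.ones((1, 7, 7, 7, 7, 1))
        w = np.ones((3, 3, 3, 3, 1, 1))
        y = conv4d(x, w)
        assert y[0, 3, 3, 3, 3, 0] == pytest.approx(81.0)  # 3^4 taps

    @pytest.mark.parametrize("stride", [1, 2, (1, 2, 1, 2)])
    def test_matches_nested_sum_oracle(self, rng, stride):
        x = rng.normal(size=(2, 5, 6, 6, 6, 2)).astype(np.float32)
        w = rng.normal(size=(3, 3, 3, 3, 2, 3)).astype(np.float32)
        got = conv4d(x, w, stride=stride)
        want = conv4d_reference(x, w, stride)
        assert got.shape == want.shape
        assert np.abs(got - want).max() < 1e-5

    def test_larger_random_case_against_oracle(self, rng):
        x = rng.normal(size=(1, 6, 6, 6, 6, 3)).astype(np.float32)
        w = rng.normal(size=(3, 3, 3, 3, 3, 2)).astype(np.float32)
        assert np.abs(conv4d(x, w) - conv4d_reference(x, w)).max() < 1e-5

    def test_bias_and_shape_errors(self, rng):
        x = rng.normal(size=(1, 4, 4, 4, 4, 2))
        w = rng.normal(size=(3, 3, 3, 3, 2, 2))
        y0 = conv4d(x, w)
        y1 = conv4d(x, w, b=np.array([1.0, -1.0]))
        assert np.allclose(y1 - y0, np.array([1.0, -1.0]), atol=1e-10)
        with pytest.raises(ShapeError):
            conv4d(x, rng.normal(size=(3, 3, 3, 3, 5, 2)))
        with pytest.raises(ConfigurationError):
            conv4d(x, rng.normal(size=(2, 3, 3, 3, 2, 2)))


class TestDenseBlock:
    @pytest.mark.parametrize("cin, expected", [(8, 32), (1, 25)])
    def test_channel_growth(self, rng, cin, expected):
        block = DenseBlock(cin, 3, 8, 3, rng, np.float64, "b")
        x = rng.normal(size=(1, 3, 4, 4, 4, cin))
        y = block.forward(x, training=False)
        assert y.shape == (1, 3, 4, 4, 4, expected)
        assert block.cout == expected

    def test_preserves_extents(self, rng):
        block = DenseBlock(2, 3, 4, 3, rng, np.float64, "b")
        x = rng.normal(size=(2, 5, 3, 6, 4, 2))
        assert block.forward(x, training=False).shape[:5] == x.shape[:5]

    def test_block_input_passes_through_concatenation(self, rng):
        block = DenseBlock(2, 2, 3, 3, rng, np.float64, "b")
        x = rng.normal(size=(1, 2, 3, 3, 3, 2))
        y = block.forward(x, training=False)
        assert np.array_equal(y[..., :2], x)


class TestTransitionPooling:
    def test_halves_every_axis(self, rng):
        pool = AvgPool4d()
        x = rng.normal(size=(1, 10, 32, 32, 32, 2)).astype(np.float32)
        assert pool.forward(x, training=False).shape == (1, 5, 16, 16, 16, 2)

    def test_constant_preserved(self):
        pool = AvgPool4d()
        x = np.full((1, 4, 4, 4, 4, 3), 1.75)
        y = pool.forward(x, training=False)
        assert np.allclose(y, 1.75)

    def test_degenerate_axis_passes_through(self, rng):
        pool = AvgPool4d()
        x = rng.normal(size=(1, 1, 4, 4, 4, 2))
        assert pool.forward(x, training=False).shape == (1, 1, 2, 2, 2, 2)

    def test_odd_extent_drops_trailing_sample(self, rng):
        pool = AvgPool4d()
        x = rng.normal(size=(1, 5, 4, 4, 4, 1))
        y = pool.forward(x, training=True)
        assert y.shape == (1, 2, 2, 2, 2, 1)
        assert pool.backward(np.ones_like(y)).shape == x.shape


class TestModel:
    def test_forward_scalar_per_item(self, rng):
        spec = ModelSpec(input_shape=(4, 6, 6, 6), stem_layers=2, stem_channels=3,
                         growth_rate=2, layers_per_block=2)
        model = build_model(spec, 0)
        x = rng.normal(size=(3, 4, 6, 6, 6)).astype(np.float32)
        pred = model.forward(x)
        assert pred.shape == (3,)
        assert np.all(np.isfinite(pred))

    def test_single_conv_parameter_count(self, rng):
        # one 3^4 kernel, 1 -> 8 channels, plus bias: 81*8 + 8 = 656
        from oce4d.net4d import Conv4d

        layer = Conv4d(1, 8, 3, rng)
        assert sum(p.value.size for p in layer.params()) == 656

    def test_same_seed_identical_parameters(self):
        spec = ModelSpec(input_shape=(4, 6, 6, 6), stem_channels=4, growth_rate=4)
        a, b = build_model(spec, 42), build_model(spec, 42)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)
        c = build_model(spec, 43)
        assert any(
            not np.array_equal(pa.value, pc.value)
            for pa, pc in zip(a.params(), c.params())
        )

    def test_zeroed_head_predicts_zero(self, rng):
        spec = ModelSpec(input_shape=(4, 6, 6, 6), stem_layers=1, stem_channels=2,
                         growth_rate=2, layers_per_block=1)
        model = build_model(spec, 0)
        head = model.layers[-1]
        head.w.value[...] = 0.0
        head.b.value[...] = 0.0
        x = rng.normal(size=(2, 4, 6, 6, 6)).astype(np.float32)
        assert np.allclose(model.forward(x), 0.0)

    def test_identical_items_identical_predictions(self, rng):
        spec = ModelSpec(input_shape=(4, 6, 6, 6), stem_layers=1, stem_channels=2,
                         growth_rate=2, layers_per_block=1)
        model = build_model(spec, 0)
        item = rng.normal(size=(4, 6, 6, 6)).astype(np.float32)
        batch = np.stack([item, item, item])
        pred = model.forward(batch, training=False)
        assert pred[0] == pred[1] == pred[2]

    def test_gap_head_constant_shift_identity(self, rng):
        """Adding kappa to all post-GAP features shifts the output by
        kappa * sum(head weights)."""
        gap, head = GlobalAvgPool(), Linear(5, 1, rng, np.float64)
        feats = rng.normal(size=(3, 2, 2, 2, 2, 5))
        base = head.forward(gap.forward(feats, False), False)
        kappa = 0.7
        shifted = head.forward(gap.forward(feats, False) + kappa, False)
        assert np.allclose(shifted - base, kappa * head.w.value.sum(), atol=1e-12)

    def test_downsampling_exhaustion_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(input_shape=(4, 6, 6, 0))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        spec = ModelSpec(input_shape=(4, 6, 6, 6), stem_layers=1, stem_channels=2,
                         growth_rate=2, layers_per_block=1)
        model = build_model(spec, 7)
        x = rng.normal(size=(2, 4, 6, 6, 6)).astype(np.float32)
        want = model.forward(x)
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(path, model, extra={"note": "test"})
        loaded, extra = load_checkpoint(path)
        assert extra == {"note": "test"}
        assert np.allclose(loaded.forward(x), want)
        assert loaded.n_parameters == model.n_parameters


class TestGradients:
    def test_finite_difference_gradient_check(self, rng):
        """Backprop gradient of the MSE loss against central differences on a
        tiny double-precision model."""
        spec = ModelSpec(input_shape=(3, 4, 4, 4), stem_layers=1, stem_channels=2,
                         n_blocks=2, layers_per_block=1, growth_rate=2,
                         dtype="float64")
        model = build_model(spec, 3)
        x = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float64)
        y = np.array([1.0, 2.0])

        def loss():
            pred = model.forward(x, training=True)
            return float(np.mean((pred - y) ** 2)), pred

        model.zero_grad()
        val, pred = loss()
        model.backward(2.0 * (pred - y) / y.size)

        eps = 1e-5
        checked = 0
        for p in model.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss()
                flat[idx] = orig - eps
                lm, _ = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                if abs(num) < 1e-8 and abs(gflat[idx]) < 1e-8:
                    continue
                assert gflat[idx] == pytest.approx(num, rel=1e-3, abs=1e-7)
                checked += 1
        assert checked >= 10
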