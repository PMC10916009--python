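"""Numpy NN toolkit: losses, layer gradients, optimiser, training loop."""

import numpy as np
import pytest

from coa_surrogate.errors import ParameterError
from coa_surrogate.nn import (
    Adam,
    BatchNorm,
    BiLSTM,
    Conv3D,
    ConvTranspose3D,
    Dense,
    EarlyStopping,
    ExponentialDecay,
    LeakyReLU,
    MaxPool3D,
    ReLU,
    fit_model,
    masked_rmse,
    masked_rmse_grad,
)


class TestMaskedRmse:
    def test_hand_example(self):
        pred = np.array([3.0, 0.0])
        target = np.array([0.0, 4.0])
        assert masked_rmse(pred, target, np.array([True, True])) == pytest.approx(
            3.5355, abs=1e-4
        )

    def test_ignores_padding_garbage(self):
        pred = np.array([1.0, 2.0, 9e9])
        target = np.array([1.0, 2.0, 0.0])
        mask = np.array([True, True, False])
        assert masked_rmse(pred, target, mask) == 0.0

    def test_equals_plain_rmse_with_full_mask(self):
        rng = np.random.default_rng(0)
        pred = rng.normal(size=(4, 7))
        target = rng.normal(size=(4, 7))
        full = np.ones((4, 7), dtype=bool)
        assert masked_rmse(pred, target, full) == pytest.approx(
            np.sqrt(np.mean((pred - target) ** 2))
        )

    def test_bruteforce_equivalence(self):
        # reference implementation: explicit loop over valid entries
        rng = np.random.default_rng(42)
        for _ in range(10):
            pred = rng.normal(size=(3, 12, 8))
            target = rng.normal(size=(3, 12, 8))
            mask = rng.random((3, 12)) < 0.6
            mask[:, 0] = True  # never empty
            sq, n = 0.0, 0
            for c in range(3):
                for t in range(12):
                    if mask[c, t]:
                        for k in range(8):
                            sq += (pred[c, t, k] - target[c, t, k]) ** 2
                            n += 1
            assert abs(masked_rmse(pred, target, mask) - np.sqrt(sq / n)) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        pred = rng.normal(size=20)
        target = rng.normal(size=20)
        mask = np.ones(20, dtype=bool)
        perm = rng.permutation(20)
        assert masked_rmse(pred, target, mask) == pytest.approx(
            masked_rmse(pred[perm], target[perm], mask)
        )

    def test_empty_mask_raises(self):
        with pytest.raises(ParameterError):
            masked_rmse(np.ones(3), np.ones(3), np.zeros(3, dtype=bool))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        pred = rng.normal(size=(2, 6, 4))
        target = rng.normal(size=(2, 6, 4))
        mask = rng.random((2, 6)) < 0.7
        mask[:, 0] = True
        loss, grad = masked_rmse_grad(pred, target, mask)
        eps = 1e-6
        for idx in [(0, 0, 1), (1, 3, 2), (0, 5, 0)]:
            p = pred.copy()
            p[idx] += eps
            up = masked_rmse(p, target, mask)
            p[idx] -= 2 * eps
            dn = masked_rmse(p, target, mask)
            assert grad[idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)


def _num_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        up = f()
        arr[idx] = orig - eps
        dn = f()
        arr[idx] = orig
        g[idx] = (up - dn) / (2 * eps)
    return g


def _check_layer_gradients(layer, x, tol=1e-6):
    """Compare backward() against central differences for inputs and params."""
    rng = np.random.default_rng(99)
    out = layer.forward(x, train=True)
    target = rng.normal(size=out.shape)
    mask = np.ones(out.shape, dtype=bool)

    def loss():
        return masked_rmse(layer.forward(x, train=True), target, mask)

    _, dout = masked_rmse_grad(layer.forward(x, train=True), target, mask)
    layer.zero_grad()
    dx = layer.backward(dout)

    dx_num = _num_grad(loss, x)
    scale = max(1.0, np.abs(dx_num).max())
    assert np.abs(dx - dx_num).max() / scale < tol

    for name, p in layer.params.items():
        g_num = _num_grad(loss, p.value)
        scale = max(1.0, np.abs(g_num).max())
        assert np.abs(p.grad - g_num).max() / scale < tol, name


class TestLayerGradients:
    def test_dense(self):
        rng = np.random.default_rng(0)
        layer = Dense(3, 4, rng, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(2, 5, 3)))

    def test_leaky_relu(self):
        rng = np.random.default_rng(0)
        _check_layer_gradients(LeakyReLU(0.3), rng.normal(size=(2, 5, 3)) + 0.1)

    def test_relu(self):
        rng = np.random.default_rng(0)
        _check_layer_gradients(ReLU(), rng.normal(size=(2, 4, 3)) + 0.1)

    def test_bilstm(self):
        rng = np.random.default_rng(0)
        layer = BiLSTM(3, 4, rng, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(2, 6, 3)), tol=1e-5)

    def test_conv3d(self):
        rng = np.random.default_rng(0)
        layer = Conv3D(2, 3, rng, k=3, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(1, 4, 4, 4, 2)))

    def test_conv3d_1x1(self):
        rng = np.random.default_rng(0)
        layer = Conv3D(3, 2, rng, k=1, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(1, 3, 3, 3, 3)))

    def test_conv_transpose3d(self):
        rng = np.random.default_rng(0)
        layer = ConvTranspose3D(3, 2, rng, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(1, 2, 2, 2, 3)))

    def test_maxpool3d(self):
        rng = np.random.default_rng(0)
        # distinct values so the argmax selection is unambiguous
        x = rng.permutation(4 * 4 * 4 * 2).astype(float).reshape(1, 4, 4, 4, 2)
        _check_layer_gradients(MaxPool3D(), x)

    def test_batchnorm_train_mode(self):
        rng = np.random.default_rng(0)
        layer = BatchNorm(3, dtype=np.float64)
        _check_layer_gradients(layer, rng.normal(size=(2, 2, 2, 2, 3)), tol=1e-5)


class TestShapes:
    def test_maxpool_halves_each_spatial_dim(self):
        x = np.random.default_rng(0).normal(size=(2, 4, 6, 8, 3))
        out = MaxPool3D().forward(x)
        assert out.shape == (2, 2, 3, 4, 3)
        assert np.all(out == x.reshape(2, 2, 2, 3, 2, 4, 2, 3).max(axis=(2, 4, 6)))

    def test_conv_transpose_doubles_each_spatial_dim(self):
        rng = np.random.default_rng(0)
        layer = ConvTranspose3D(3, 2, rng)
        out = layer.forward(rng.normal(size=(1, 2, 3, 4, 3)).astype(np.float32))
        assert out.shape == (1, 4, 6, 8, 2)

    def test_batchnorm_normalises_in_train_mode(self):
        rng = np.random.default_rng(0)
        layer = BatchNorm(2, dtype=np.float64)
        x = rng.normal(loc=5.0, scale=3.0, size=(4, 8, 2))
        out = layer.forward(x, train=True)
        assert abs(out.reshape(-1, 2).mean(axis=0)).max() < 1e-8
        assert np.allclose(out.reshape(-1, 2).std(axis=0), 1.0, atol=1e-6)


class TestOptim:
    def test_exponential_decay_schedule(self):
        sched = ExponentialDecay(1e-3, 0.96)
        assert sched(0) == 1e-3
        assert sched(1) == pytest.approx(0.96e-3)
        assert sched(10) == pytest.approx(1e-3 * 0.96**10)

    def test_adam_minimises_quadratic(self):
        from coa_surrogate.nn import Param

        p = Param(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            p.grad[...] = 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-3


class TestTraining:
    def test_patience_semantics_stop_at_epoch_21(self):
        stopper = EarlyStopping(patience=20)
        stops = [stopper.update(1.0 + 0.1 * k) for k in range(25)]
        # the first epoch sets the best; 20 non-improving epochs follow
        assert stops.index(True) == 20  # i.e. the 21st epoch

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(1.0)
        assert not stopper.update(1.1)
        assert not stopper.update(0.9)  # improvement resets
        assert not stopper.update(1.0)
        assert stopper.update(1.0)

    def _toy(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 10, 2)).astype(np.float32)
        W = np.array([[1.0, -2.0, 0.5], [0.3, 1.5, -1.0]], dtype=np.float32)
        y = X @ W
        mask = np.ones((30, 10), dtype=bool)
        from coa_surrogate.models import _SequentialNet

        net = _SequentialNet([Dense(2, 3, np.random.default_rng(0))])
        return net, X, y, mask

    def test_same_seed_identical_losses(self):
        results = []
        for _ in range(2):
            net, X, y, mask = self._toy(7)
            hist = fit_model(
                net, X[:24], y[:24], mask[:24], X[24:], y[24:], mask[24:],
                lr_init=0.01, max_epochs=5, rng=np.random.default_rng(3),
            )
            results.append((hist.train_loss, hist.val_loss))
        assert results[0] == results[1]

    def test_learns_affine_map(self):
        net, X, y, mask = self._toy(11)
        hist = fit_model(
            net, X[:24], y[:24], mask[:24], X[24:], y[24:], mask[24:],
            lr_init=0.05, lr_decay=1.0, batch_size=8, max_epochs=200,
            rng=np.random.default_rng(0),
        )
        assert hist.best_val_loss < 0.1

    def test_best_weights_restored(self):
        # after training, the model's validation loss equals the best seen
        net, X, y, mask = self._toy(13)
        hist = fit_model(
            net, X[:24], y[:24], mask[:24], X[24:], y[24:], mask[24:],
            lr_init=0.05, max_epochs=30, rng=np.random.default_rng(1),
        )
        val = masked_rmse(net.forward(X[24:], train=False), y[24:], mask[24:])
        assert val == pytest.approx(hist.best_val_loss, abs=1e-6)

    def test_empty_sets_rejected(self):
        net, X, y, mask = self._toy(1)
        with pytest.raises(ParameterError):
            fit_model(net, X[:0], y[:0], mask[:0], X, y, mask)


class TestBiLSTMBehaviour:
    def test_zero_padded_timesteps_finite(self):
        rng = np.random.default_rng(0)
        layer = BiLSTM(7, 8, rng)
        x = np.zeros((2, 20, 7), dtype=np.float32)
        out = layer.forward(x, train=False)
        assert out.shape == (2, 20, 16)
        assert np.all(np.isfinite(out))

    def test_bidirectional_concatenation(self):
        # the first half of the feature axis is the forward pass: it must
        # be causal (independent of future inputs); the backward half is not
        rng = np.random.default_rng(0)
        layer = BiLSTM(2, 3, rng)
        x = rng.normal(size=(1, 10, 2)).astype(np.float32)
        base = layer.forward(x, train=False)
        x2 = x.copy()
        x2[0, 7, :] += 1.0  # perturb a late timestep
        out = layer.forward(x2, train=False)
        assert np.allclose(out[0, :7, :3], base[0, :7, :3])  # forward half
        assert not np.allclose(out[0, :7, 3:], base[0, :7, 3:])  # backward half
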