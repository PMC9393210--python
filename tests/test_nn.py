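import numpy as np
import pytest
from scipy.signal import correlate2d

from fhrfusion import nn


def forward_chain(layers, x, training=False, rng=None):
    """Run a layer list without the float32 cast, for float64 grad checks."""
    rng = rng or np.random.default_rng(0)
    for layer in layers:
        x = layer.forward(x, training, rng)
    return x


def to_float64(layers):
    for layer in layers:
        for k in layer.params:
            layer.params[k] = layer.params[k].astype(np.float64)
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = layer.running_mean.astype(np.float64)
            layer.running_var = layer.running_var.astype(np.float64)


def numeric_grad_check(layers, x, y, n_checks=20, eps=1e-6, tol=1e-5):
    """Central-difference check of every layer's parameter gradients."""
    to_float64(layers)
    rng = np.random.default_rng(0)

    def loss_at():
        probs = forward_chain(layers, x, training=True, rng=np.random.default_rng(0))
        loss, _ = nn.cross_entropy(probs, y)
        return loss + sum(layer.penalty() for layer in layers)

    probs = forward_chain(layers, x, training=True, rng=np.random.default_rng(0))
    _, grad = nn.cross_entropy(probs, y)
    for layer in reversed(layers):
        grad = layer.backward(grad)

    check_rng = np.random.default_rng(1)
    for layer in layers:
        for name, value in layer.params.items():
            flat = value.reshape(-1)
            g = layer.grads[name].reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(n_checks, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_at()
                flat[idx] = orig - eps
                lm = loss_at()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], abs=tol), f"{type(layer).__name__}.{name}[{idx}]"


def onehot(labels):
    out = np.zeros((len(labels), 2))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class TestLayers:
    def test_softmax_rows_normalize_and_shift_invariance(self):
        x = np.random.default_rng(0).normal(size=(5, 2))
        sm = nn.Softmax()
        y = sm.forward(x, False, None)
        np.testing.assert_allclose(y.sum(axis=1), 1.0, atol=1e-12)
        y2 = nn.Softmax().forward(x + 100.0, False, None)
        np.testing.assert_allclose(y, y2, atol=1e-12)

    def test_cross_entropy_hand_value(self):
        probs = np.array([[0.8, 0.2], [0.4, 0.6]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        loss, _ = nn.cross_entropy(probs, y)
        assert loss == pytest.approx(-(np.log(0.8) + np.log(0.6)) / 2)

    def test_conv2d_matches_scipy_correlate(self):
        rng = np.random.default_rng(2)
        conv = nn.Conv2D(1, 1, 3, rng)
        x = rng.normal(size=(1, 8, 8, 1))
        out = conv.forward(x, False, rng)
        kernel = conv.params["W"].reshape(3, 3)
        ref = correlate2d(x[0, :, :, 0], kernel, mode="valid") + conv.params["b"][0]
        np.testing.assert_allclose(out[0, :, :, 0], ref, rtol=1e-5)

    def test_maxpool_hand_example(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        pool = nn.MaxPool2D(2)
        assert pool.forward(x, False, None)[0, 0, 0, 0] == 4.0
        # gradient routes only to the argmax position
        dx = pool.backward(np.ones((1, 1, 1, 1)))
        np.testing.assert_array_equal(dx[0, :, :, 0], [[0, 0], [0, 1]])

    def test_batchnorm_standardizes_in_training(self):
        rng = np.random.default_rng(3)
        bn = nn.BatchNorm(4)
        x = rng.normal(5.0, 3.0, size=(200, 4)).astype(np.float32)
        y = bn.forward(x, True, rng)
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.std(axis=0), 1.0, atol=1e-3)

    def test_batchnorm_eval_uses_running_stats(self):
        rng = np.random.default_rng(4)
        bn = nn.BatchNorm(2)
        x = rng.normal(3.0, 2.0, size=(500, 2)).astype(np.float32)
        for _ in range(50):
            bn.forward(x, True, rng)
        y = bn.forward(x, False, rng)
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=0.05)

    def test_dropout_eval_is_identity(self):
        d = nn.Dropout(0.5)
        x = np.ones((10, 10))
        np.testing.assert_array_equal(d.forward(x, False, np.random.default_rng(0)), x)

    def test_dropout_training_preserves_expectation(self):
        d = nn.Dropout(0.4)
        x = np.ones((400, 400), dtype=np.float32)
        y = d.forward(x, True, np.random.default_rng(5))
        kept = y > 0
        assert kept.mean() == pytest.approx(0.6, abs=0.01)
        np.testing.assert_allclose(y[kept], 1.0 / 0.6, rtol=1e-6)

    def test_dropout_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            nn.Dropout(1.0)

    def test_dense_penalty_value(self):
        rng = np.random.default_rng(6)
        d = nn.Dense(3, 2, rng, l1=0.01, l2=0.1)
        w = d.params["W"]
        assert d.penalty() == pytest.approx(0.01 * np.abs(w).sum() + 0.1 * (w**2).sum(), rel=1e-6)


class TestGradients:
    def test_dense_relu_softmax_chain(self):
        rng = np.random.default_rng(10)
        layers = [
            nn.Dense(6, 8, rng),
            nn.ReLU(),
            nn.Dense(8, 2, rng, l1=1e-3, l2=1e-2),
            nn.Softmax(),
        ]
        x = rng.normal(size=(7, 6))
        numeric_grad_check(layers, x, onehot(rng.integers(0, 2, 7)))

    def test_batchnorm_chain(self):
        rng = np.random.default_rng(11)
        layers = [nn.Dense(5, 6, rng), nn.BatchNorm(6), nn.ReLU(), nn.Dense(6, 2, rng), nn.Softmax()]
        x = rng.normal(size=(9, 5))
        numeric_grad_check(layers, x, onehot(rng.integers(0, 2, 9)))

    def test_conv_pool_chain(self):
        rng = np.random.default_rng(12)
        layers = [
            nn.Conv2D(2, 3, 3, rng),
            nn.ReLU(),
            nn.MaxPool2D(2),
            nn.Flatten(),
            nn.Dense(3 * 3 * 3, 2, rng),
            nn.Softmax(),
        ]
        x = rng.normal(size=(4, 8, 8, 2))
        numeric_grad_check(layers, x, onehot(rng.integers(0, 2, 4)))

    def test_input_gradient_of_dense(self):
        rng = np.random.default_rng(13)
        layers = [nn.Dense(4, 2, rng), nn.Softmax()]
        to_float64(layers)
        x = rng.normal(size=(3, 4))
        y = onehot(np.array([0, 1, 0]))
        probs = forward_chain(layers, x, training=True)
        _, grad = nn.cross_entropy(probs, y)
        for layer in reversed(layers):
            grad = layer.backward(grad)
        eps = 1e-6
        for i, j in [(0, 0), (1, 2), (2, 3)]:
            xp, xm = x.copy(), x.copy()
            xp[i, j] += eps
            xm[i, j] -= eps
            lp, _ = nn.cross_entropy(forward_chain(layers, xp, training=True), y)
            lm, _ = nn.cross_entropy(forward_chain(layers, xm, training=True), y)
            assert (lp - lm) / (2 * eps) == pytest.approx(grad[i, j], abs=1e-7)


class TestAdam:
    def test_hyperbolic_lr_schedule(self):
        opt = nn.Adam(lr=1e-4, decay=1e-4 / 200)
        assert opt.lr_at(0) == 1e-4
        assert opt.lr_at(200) == pytest.approx(1e-4 / 1.0001)

    def test_single_step_matches_closed_form(self):
        rng = np.random.default_rng(14)
        layer = nn.Dense(2, 2, rng)
        net = nn.Sequential([layer])
        w0 = layer.params["W"].astype(np.float64).copy()
        g = np.ones_like(layer.params["W"])
        layer.grads = {"W": g, "b": np.zeros(2, dtype=np.float32)}
        opt = nn.Adam(lr=0.01, decay=0.0)
        opt.step(net, epoch=0)
        # first Adam step is -lr * g / (|g| + eps) = -lr for unit gradients
        np.testing.assert_allclose(layer.params["W"], w0 - 0.01, atol=1e-6)


class TestFit:
    def make_data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        x = rng.normal(size=(n, 4)) + 3.0 * labels[:, None]
        return x.astype(np.float32), onehot(labels)

    def make_net(self, seed=0):
        rng = np.random.default_rng(seed)
        return nn.Sequential([nn.Dense(4, 8, rng), nn.ReLU(), nn.Dense(8, 2, rng), nn.Softmax()])

    def test_training_is_deterministic_under_a_seed(self):
        x, y = self.make_data()
        nets = [self.make_net(seed=1) for _ in range(2)]
        for net in nets:
            nn.fit(net, x, y, x, y, max_epochs=3, seed=42, optimizer=nn.Adam(lr=1e-2))
        for la, lb in zip(nets[0].layers, nets[1].layers):
            for k in la.params:
                np.testing.assert_array_equal(la.params[k], lb.params[k])

    def test_loss_decreases_on_separable_data(self):
        x, y = self.make_data()
        net = self.make_net(seed=2)
        hist = nn.fit(net, x, y, max_epochs=20, seed=0, optimizer=nn.Adam(lr=1e-2))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.train_acc[-1] > 0.9

    def test_early_stopping_and_best_weight_restore(self):
        x, y = self.make_data()
        rng = np.random.default_rng(3)
        xv = rng.normal(size=(40, 4)).astype(np.float32)  # unlearnable validation noise
        yv = onehot(rng.integers(0, 2, 40))
        net = self.make_net(seed=3)
        hist = nn.fit(net, x, y, xv, yv, max_epochs=50, patience=2, seed=0,
                      optimizer=nn.Adam(lr=5e-2))
        assert hist.stopped_epoch is not None
        assert hist.epochs_run < 50
        # restored weights reproduce the best recorded validation loss
        loss, _ = nn.evaluate_loss(net, xv, yv)
        assert loss == pytest.approx(min(hist.val_loss), abs=1e-5)

    def test_max_epochs_zero_leaves_model_untouched(self):
        x, y = self.make_data()
        net = self.make_net(seed=4)
        w0 = net.layers[0].params["W"].copy()
        hist = nn.fit(net, x, y, max_epochs=0, seed=0)
        assert hist.epochs_run == 0
        np.testing.assert_array_equal(net.layers[0].params["W"], w0)

    def test_single_class_training_set_rejected(self):
        x = np.zeros((10, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            nn.fit(self.make_net(), x, onehot(np.zeros(10, dtype=int)))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            nn.fit(self.make_net(), np.zeros((0, 4)), np.zeros((0, 2)))
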