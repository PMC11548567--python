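"""Training engine: gradients, losses, determinism, Model/Results contracts."""

import numpy as np
import pytest

from lungsound import nn
from lungsound.arch import ArchSpec, LayerSpec, default_arch, summarize
from lungsound.model import CNNResults, LungSoundCNN, TrainConfig, build, one_hot
from lungsound.preprocess import DatasetMatrix


def tiny_arch(input_len=40, n_classes=3):
    return ArchSpec(
        input_len=input_len,
        input_channels=1,
        layers=(
            LayerSpec("conv1d", filters=3, kernel=5, activation="relu"),
            LayerSpec("maxpool1d", pool=2),
            LayerSpec("flatten"),
            LayerSpec("dense", units=8, activation="relu"),
            LayerSpec("dense", units=n_classes, activation="softmax"),
        ),
    )


def test_backprop_matches_numeric_gradient():
    """Finite-difference check of every parameter gradient on a tiny net."""
    rng = np.random.default_rng(0)
    net = nn.Network(tiny_arch(), np.random.default_rng(1))
    # float64 weights for a tight finite-difference comparison
    for layer in net.layers:
        for p in layer.params:
            p[...] = p.astype(np.float64)
    x = rng.normal(size=(4, 40)).astype(np.float32)
    y = one_hot(np.array([0, 1, 2, 0]), 3)

    probs = net.forward(x, train=False)
    grads = net.backward(probs, y, "categorical_crossentropy", 0.0)

    eps = 1e-3
    params = net.trainable_params
    for p, g in zip(params, grads):
        flat = p.reshape(-1)
        for idx in rng.choice(flat.size, size=min(10, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = nn.cross_entropy(net.forward(x), y)
            flat[idx] = orig - eps
            lm = nn.cross_entropy(net.forward(x), y)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert g.reshape(-1)[idx] == pytest.approx(numeric, abs=2e-3)


def test_forward_probabilities_normalized():
    net = nn.Network(tiny_arch(), np.random.default_rng(0))
    probs = net.forward(np.random.default_rng(1).normal(size=(7, 40)))
    assert probs.shape == (7, 3)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.all(probs >= 0)


def test_default_arch_forward_shape_and_param_equivalence():
    cfg = TrainConfig(seed=0)
    net = build(default_arch(), cfg)
    assert net.param_count == summarize(default_arch()).total_params
    probs = net.forward(np.zeros((2, 8000), dtype=np.float32))
    assert probs.shape == (2, 4)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(10, 4))
        probs = nn.softmax(logits)
        y = one_hot(rng.integers(0, 4, 10))
        assert nn.focal_loss(probs, y, 0.0) == pytest.approx(nn.cross_entropy(probs, y))

    def test_certain_predictions_zero_loss(self):
        y = one_hot(np.array([0, 1]))
        assert nn.focal_loss(y.copy(), y, 2.0) == pytest.approx(0.0, abs=1e-5)

    def test_direct_substitution(self):
        # two classes at (0.5, 0.5), true class 0, gamma 2 -> 0.25 * (-log 0.5)
        probs = np.array([[0.5, 0.5]])
        y = np.array([[1.0, 0.0]])
        assert nn.focal_loss(probs, y, 2.0) == pytest.approx(0.25 * -np.log(0.5))

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            nn.focal_loss(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]]), -1.0)

    def test_focal_gradient_matches_numeric(self):
        rng = np.random.default_rng(3)
        net = nn.Network(tiny_arch(), np.random.default_rng(4))
        x = rng.normal(size=(3, 40)).astype(np.float32)
        y = one_hot(np.array([0, 1, 2]), 3)
        probs = net.forward(x)
        grads = net.backward(probs, y, "focal", 2.0)
        eps = 1e-3
        p = net.trainable_params[0]
        flat = p.reshape(-1)
        for idx in rng.choice(flat.size, size=5, replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = nn.focal_loss(net.forward(x), y, 2.0)
            flat[idx] = orig - eps
            lm = nn.focal_loss(net.forward(x), y, 2.0)
            flat[idx] = orig
            assert grads[0].reshape(-1)[idx] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)


def _toy_data(n=40, length=64, seed=0):
    """Two-band toy problem: class = which half of the clip carries energy."""
    rng = np.random.default_rng(seed)
    X = rng.normal(scale=0.05, size=(n, length)).astype(np.float32)
    y = np.arange(n) % 3
    for i, lbl in enumerate(y):
        lo = lbl * (length // 3)
        X[i, lo : lo + length // 3] += 1.0
    return DatasetMatrix(X, y)


def test_fit_learns_separable_toy_problem():
    data = _toy_data(60, seed=1)
    arch = tiny_arch(input_len=64)
    model = LungSoundCNN(data, val=data, arch=arch, config=TrainConfig(epochs=40, seed=0))
    res = model.fit()
    assert res.history["accuracy"][-1] >= 0.9


def test_zero_epochs_gives_untrained_model_empty_history():
    data = _toy_data(12)
    model = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=TrainConfig(epochs=0, seed=0))
    res = model.fit()
    assert res.history["loss"] == []
    assert "untrained" in res.summary()


def test_same_seed_identical_history():
    data = _toy_data(24, seed=5)
    cfg = TrainConfig(epochs=5, seed=3)
    h1 = LungSoundCNN(data, val=data, arch=tiny_arch(input_len=64), config=cfg).fit().history
    h2 = LungSoundCNN(data, val=data, arch=tiny_arch(input_len=64), config=cfg).fit().history
    assert h1 == h2


def test_non_finite_loss_aborts_with_diagnostic():
    data = _toy_data(24)
    data.X[3, 10] = np.nan  # corrupt input propagates to a non-finite loss
    cfg = TrainConfig(epochs=5, seed=0)
    model = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=cfg)
    with pytest.raises(FloatingPointError, match="non-finite loss"):
        model.fit()


def test_input_length_mismatch_rejected():
    data = _toy_data(12, length=32)
    with pytest.raises(ValueError, match="expects"):
        LungSoundCNN(data, arch=tiny_arch(input_len=64))


def test_weights_round_trip(tmp_path):
    data = _toy_data(12)
    res = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=TrainConfig(epochs=2, seed=0)).fit()
    before = res.predict_proba(data.X, mc_samples=0)
    res.save_weights(tmp_path / "w.npz")
    res2 = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=TrainConfig(epochs=0, seed=9)).fit()
    res2.load_weights(tmp_path / "w.npz")
    np.testing.assert_allclose(res2.predict_proba(data.X, mc_samples=0), before, atol=1e-6)


def test_mc_dropout_prediction_deterministic():
    data = _toy_data(12)
    res = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=TrainConfig(epochs=2, seed=0)).fit()
    a = res.predict_proba(data.X)
    b = res.predict_proba(data.X)
    np.testing.assert_allclose(a, b)
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-6)


def test_summary_contains_layer_table():
    data = _toy_data(12)
    res = LungSoundCNN(data, arch=tiny_arch(input_len=64), config=TrainConfig(epochs=1, seed=0)).fit()
    text = res.summary()
    assert "conv1d" in text and "dense" in text
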