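"""Classifier tests: attention arithmetic, activations, loss, training."""

import numpy as np
import pytest

import oriforge as of
from oriforge.nn import softmax

from conftest import TINY_CCONFIG, tiny_tconfig


# ------------------------------------------------------ attention primitive
def test_attention_single_key_returns_value():
    q = np.random.default_rng(0).normal(size=(4, 3))
    k = np.ones((1, 3))
    v = np.array([[2.0, -1.0]])
    out = of.scaled_dot_attention(q, k, v)
    np.testing.assert_allclose(out, np.tile(v, (4, 1)))


def test_attention_identical_keys_average_values():
    rng = np.random.default_rng(1)
    q = rng.normal(size=(5, 3))
    k = np.tile(rng.normal(size=(1, 3)), (4, 1))
    v = rng.normal(size=(4, 2))
    np.testing.assert_allclose(
        of.scaled_dot_attention(q, k, v), np.tile(v.mean(axis=0), (5, 1)), atol=1e-12
    )


def test_attention_identity_hand_computed():
    eye = np.eye(2)
    out = of.scaled_dot_attention(eye, eye, eye)
    # softmax over (1/sqrt(2), 0) -> e^0.7071 / (e^0.7071 + 1)
    np.testing.assert_allclose(out[0], [0.6698, 0.3302], atol=1e-4)


def test_attention_rows_are_distributions():
    rng = np.random.default_rng(2)
    q, k = rng.normal(size=(6, 4)), rng.normal(size=(9, 4))
    p = softmax(q @ k.T / 2.0, axis=-1)
    assert np.all(p >= 0)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_attention_shape_mismatch():
    with pytest.raises(ValueError):
        of.scaled_dot_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))


# ----------------------------------------------------------------- elu, bce
def test_elu_examples():
    assert of.elu(0.0) == 0.0
    assert of.elu(2.0) == 2.0
    np.testing.assert_allclose(of.elu(-1.0), np.exp(-1) - 1)


def test_elu_monotone_continuous_bounded():
    x = np.linspace(-10, 10, 10_000)
    y = of.elu(x, alpha=1.0)
    assert np.all(np.diff(y) >= 0)
    assert np.all(y >= -1.0)
    assert abs(of.elu(1e-9) - of.elu(-1e-9)) < 1e-8


def test_bce_examples():
    assert of.bce_loss([1], [1 - 1e-7]) < 1e-5
    np.testing.assert_allclose(of.bce_loss([1], [0.5]), np.log(2))
    np.testing.assert_allclose(of.bce_loss([0], [0.5]), np.log(2))


def test_bce_flip_invariance():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=50)
    p = rng.uniform(0.01, 0.99, size=50)
    np.testing.assert_allclose(of.bce_loss(y, p), of.bce_loss(1 - y, 1 - p))


# ---------------------------------------------------------------- the model
def test_build_is_seed_reproducible():
    a = of.build_model(TINY_CCONFIG, seed=5)
    b = of.build_model(TINY_CCONFIG, seed=5)
    for pa, pb in zip(a.net.params(), b.net.params()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_default_model_has_three_attention_blocks():
    from oriforge.nn import SelfAttention

    model = of.build_model(of.ClassifierConfig(), seed=0)
    assert sum(isinstance(l, SelfAttention) for l in model.net.layers) == 3


def test_single_block_model_valid():
    cfg = of.ClassifierConfig(n_blocks=1, block=of.BlockConfig(conv_channels=4), input_dim=12)
    model = of.build_model(cfg, seed=0)
    p = model.predict_proba(np.zeros(12))
    assert 0.0 <= p <= 1.0


def test_inadmissible_input_dim_rejected():
    with pytest.raises(of.classifier.ConfigError):
        of.ClassifierConfig(input_dim=100)


def test_forward_range_determinism_batch_order():
    rng = np.random.default_rng(4)
    model = of.build_model(TINY_CCONFIG, seed=1)
    X = rng.normal(size=(7, 12))
    p1 = of.forward(X, model)
    p2 = of.forward(X, model)
    np.testing.assert_array_equal(p1, p2)
    assert np.all((p1 >= 0) & (p1 <= 1))
    singles = np.array([of.forward(x, model) for x in X])
    np.testing.assert_allclose(p1, singles)
    with pytest.raises(ValueError):
        of.forward(np.zeros(13), model)


# ----------------------------------------------------------------- training
def test_training_separates_fixture_classes(trained_tiny):
    model, Xte, yte = trained_tiny
    assert of.auc(yte, model.predict_proba(Xte)) >= 0.95


def test_training_learns(small_dataset):
    """Best-epoch validation loss does not exceed the first epoch's, 3 seeds."""
    _, X, y = small_dataset
    for seed in (0, 1, 2):
        m = of.train((X[:200], y[:200]), (X[200:], y[200:]), TINY_CCONFIG,
                     tiny_tconfig(seed=seed, max_epochs=8))
        assert min(m.history["val_loss"]) <= m.history["val_loss"][0]


def test_permuted_labels_score_near_chance(small_dataset):
    _, X, y = small_dataset
    aucs = []
    for seed in (10, 11, 12):
        rng = np.random.default_rng(seed)
        yp = rng.permutation(y)
        m = of.train((X[:200], yp[:200]), (X[200:], yp[200:]), TINY_CCONFIG,
                     tiny_tconfig(seed=seed, max_epochs=6))
        aucs.append(of.auc(yp[200:], m.predict_proba(X[200:])))
    assert 0.4 <= np.mean(aucs) <= 0.6


def test_training_is_deterministic(small_dataset):
    _, X, y = small_dataset
    runs = [
        of.train((X[:150], y[:150]), (X[150:250], y[150:250]), TINY_CCONFIG,
                 tiny_tconfig(seed=3, max_epochs=4))
        for _ in range(2)
    ]
    assert runs[0].history == runs[1].history
    for pa, pb in zip(runs[0].net.params(), runs[1].net.params()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_single_class_training_rejected(small_dataset):
    _, X, y = small_dataset
    pos = y == 1
    with pytest.raises(ValueError):
        of.train((X[pos], y[pos]), (X[:50], y[:50]), TINY_CCONFIG, tiny_tconfig())


def test_attention_ablation_trains(small_dataset):
    """The without-attention variant builds and trains alongside the full model."""
    from oriforge.nn import SelfAttention

    _, X, y = small_dataset
    cfg = of.ClassifierConfig(
        n_blocks=2, block=of.BlockConfig(conv_channels=4), mlp_hidden=(16, 8),
        input_dim=12, use_attention=False,
    )
    assert not any(isinstance(l, SelfAttention) for l in of.build_model(cfg, 0).net.layers)
    m = of.train((X[:200], y[:200]), (X[200:], y[200:]), cfg, tiny_tconfig(max_epochs=4))
    p = m.predict_proba(X[200:])
    assert np.all(np.isfinite(p)) and np.all((p >= 0) & (p <= 1))


def test_checkpoint_roundtrip_bit_identical(trained_tiny, tmp_path):
    model, Xte, _ = trained_tiny
    path = tmp_path / "model.ckpt"
    model.save(path)
    loaded = of.OriClassifier.load(path)
    np.testing.assert_array_equal(model.predict_proba(Xte), loaded.predict_proba(Xte))
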