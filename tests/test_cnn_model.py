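"""CNN mechanics: forward oracle, loss value, gradients, training descent."""

import numpy as np
import pytest

from oracles import oracle_conv2d_valid, oracle_maxpool2x2
from petromics.cnn import CNNConfig, CNNModel, SliceDataset
from petromics.cnn.network import train


def tiny_config(**kw) -> CNNConfig:
    defaults = dict(
        in_channels=2,
        feature_maps=(2, 3),
        kernel_sizes=(3, 3),
        fc_units=4,
        input_size=14,
        seed=0,
    )
    defaults.update(kw)
    return CNNConfig(**defaults)


def test_spatial_trace_of_standard_input():
    cfg = CNNConfig()
    assert cfg.input_size == 100
    assert cfg.spatial_trace() == [48, 22, 9, 2]


def test_config_validation():
    with pytest.raises(ValueError):
        CNNConfig(feature_maps=(4, 4), kernel_sizes=(5,))
    with pytest.raises(ValueError):
        CNNConfig(input_size=10)  # collapses below 1 pixel after 4 stages
    with pytest.raises(ValueError):
        CNNConfig(activation="sigmoid")


def test_zero_softmax_gives_uniform_probabilities(rng):
    model = CNNModel.initialize(tiny_config())
    x = rng.random((4, 2, 14, 14)).astype(np.float32)
    probs = model.forward(x)
    np.testing.assert_allclose(probs, 0.5, atol=1e-7)


def test_probabilities_sum_to_one(rng):
    model = CNNModel.initialize(tiny_config(seed=5))
    model.softmax_weights[:] = rng.normal(0, 1, model.softmax_weights.shape)
    x = rng.random((8, 2, 14, 14)).astype(np.float32)
    probs = model.forward(x)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_forward_matches_direct_convolution_oracle(rng):
    """Hand-unrolled conv + pool + tanh reproduces the first stage, and the
    full network reproduces a two-stage transcription."""
    cfg = tiny_config(seed=2)
    model = CNNModel.initialize(cfg, np.random.default_rng(2))
    model.softmax_weights[:] = rng.normal(0, 0.3, model.softmax_weights.shape)
    x = rng.random((2, 14, 14)).astype(np.float32)

    # stage-by-stage transcription with loop oracles
    cur = x.astype(float)
    for k, b in zip(model.kernels, model.conv_biases):
        pre = oracle_conv2d_valid(cur, k.astype(float), b.astype(float))
        cur = np.tanh(oracle_maxpool2x2(pre))  # pool/tanh commute (monotone)
    # channels-last flattening inside the network
    v = cur.transpose(1, 2, 0).reshape(-1)
    hid = np.tanh(v @ model.fc_weights.astype(float) + model.fc_bias.astype(float))
    logits = hid @ model.softmax_weights.astype(float) + model.softmax_bias.astype(float)
    expected = np.exp(logits) / np.exp(logits).sum()

    probs = model.forward(x[None])
    np.testing.assert_allclose(probs[0], expected, atol=1e-5)


def test_pooling_dominates_window(rng):
    """Each pooled activation equals the max of its 2x2 window; spatial dims
    halve exactly (floor on odd sizes)."""
    from petromics.cnn.network import _pool_forward

    x = rng.random((3, 9, 7, 2)).astype(np.float32)
    out, _ = _pool_forward(x)
    assert out.shape == (3, 4, 3, 2)
    for n in range(3):
        for c in range(2):
            ref = oracle_maxpool2x2(x[n].transpose(2, 0, 1))[c]
            np.testing.assert_allclose(out[n, :, :, c], ref)


def test_loss_at_symmetric_initialization_is_n_log_two(rng):
    model = CNNModel.initialize(tiny_config())
    n = 12
    x = rng.random((n, 2, 14, 14)).astype(np.float32)
    y = rng.integers(0, 2, n)
    assert model.loss(x, y) == pytest.approx(n * np.log(2.0), rel=1e-6)


def test_backward_matches_finite_differences(rng):
    model = CNNModel.initialize(tiny_config(seed=3), np.random.default_rng(3))
    model.softmax_weights[:] = rng.normal(0, 0.5, model.softmax_weights.shape).astype(
        np.float32
    )
    x = rng.random((5, 2, 14, 14)).astype(np.float32)
    y = np.array([0, 1, 0, 1, 1])
    probs, cache = model.forward(x, return_cache=True)
    grads = model._backward(probs, y, cache)
    eps = 1e-3
    check_rng = np.random.default_rng(0)
    for p, g in zip(model._params(), model._grad_list(grads)):
        flat, gflat = p.reshape(-1), np.asarray(g).reshape(-1)
        for idx in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = model.loss(x, y)
            flat[idx] = orig - eps
            lm = model.loss(x, y)
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gflat[idx]) < 5e-2 * max(1.0, abs(fd))


def test_single_step_descends_on_single_sample(rng):
    """One small-step SGD update on one sample lowers that sample's loss."""
    model = CNNModel.initialize(tiny_config(seed=4), np.random.default_rng(4))
    model.softmax_weights[:] = rng.normal(0, 0.3, model.softmax_weights.shape).astype(
        np.float32
    )
    x = rng.random((1, 2, 14, 14)).astype(np.float32)
    y = np.array([1])
    before = model.loss(x, y)
    probs, cache = model.forward(x, return_cache=True)
    grads = model._backward(probs, y, cache)
    lr = 1e-3
    for p, g in zip(model._params(), model._grad_list(grads)):
        p -= (lr * g).astype(p.dtype)
    assert model.loss(x, y) < before


def test_training_memorizes_small_dataset(rng):
    """A capacity-adequate network reaches 100% training accuracy on 20
    samples (overfit sanity check)."""
    n = 20
    x = rng.random((n, 2, 14, 14)).astype(np.float32)
    y = np.repeat([0, 1], n // 2)
    x[y == 1] += 0.35  # learnable offset
    ds = SliceDataset(x=x, y=y, subject=np.array(["s"] * n))
    cfg = tiny_config(
        epochs=40, learning_rate=0.05, batch_size=5, val_fraction=0.0, seed=0
    )
    model = train(ds, cfg)
    acc = (model.predict_proba(x).argmax(axis=1) == y).mean()
    assert acc == 1.0


def test_training_is_seed_deterministic(rng):
    x = rng.random((12, 2, 14, 14)).astype(np.float32)
    y = np.tile([0, 1], 6)
    ds = SliceDataset(x=x, y=y, subject=np.array(["s"] * 12))
    cfg = tiny_config(epochs=3, val_fraction=0.25, seed=8)
    m1 = train(ds, cfg)
    m2 = train(ds, cfg)
    for a, b in zip(m1._params(), m2._params()):
        np.testing.assert_array_equal(a, b)


def test_single_class_training_rejected(rng):
    x = rng.random((6, 2, 14, 14)).astype(np.float32)
    ds = SliceDataset(x=x, y=np.zeros(6, dtype=int), subject=np.array(["s"] * 6))
    with pytest.raises(ValueError, match="both classes"):
        train(ds, tiny_config(epochs=1))


def test_relu_variant_runs(rng):
    cfg = tiny_config(activation="relu", epochs=2, val_fraction=0.0, seed=1)
    x = rng.random((8, 2, 14, 14)).astype(np.float32)
    y = np.tile([0, 1], 4)
    ds = SliceDataset(x=x, y=y, subject=np.array(["s"] * 8))
    model = train(ds, cfg)
    probs = model.predict_proba(x)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_dropout_variant_runs_and_infers_deterministically(rng):
    cfg = tiny_config(dropout=0.5, epochs=2, val_fraction=0.0, seed=1)
    x = rng.random((8, 2, 14, 14)).astype(np.float32)
    y = np.tile([0, 1], 4)
    ds = SliceDataset(x=x, y=y, subject=np.array(["s"] * 8))
    model = train(ds, cfg)
    np.testing.assert_array_equal(model.predict_proba(x), model.predict_proba(x))
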