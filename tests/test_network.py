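import numpy as np
import pytest

from eitshape.network import (
    ImplicitNetwork,
    NetworkConfig,
    classify,
    decode,
    init_parameters,
    leaky_relu,
    load_model,
    measure_encoder,
    parameter_count,
    parameter_shapes,
    point_encoder,
    predict_points,
    resnet_block,
    save_model,
    softmax2,
    zero_parameters,
)
from eitshape.phantoms import NormalizationStats


class TestPrimitives:
    @pytest.mark.parametrize("x,expected", [(-2.0, -0.02), (0.0, 0.0), (3.5, 3.5)])
    def test_leaky_relu_values(self, x, expected):
        assert leaky_relu(x) == pytest.approx(expected)

    def test_softmax_symmetric_and_known_value(self):
        assert np.allclose(softmax2([0.0, 0.0]), [0.5, 0.5])
        q = softmax2([1.0, 0.0])
        assert q[0] == pytest.approx(0.7311, abs=5e-5)
        assert q[1] == pytest.approx(0.2689, abs=5e-5)

    def test_softmax_overflow_safe(self):
        q = softmax2([1000.0, 0.0])
        assert np.all(np.isfinite(q))
        assert q[0] == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "q,label", [((0.7, 0.3), 0), ((0.2, 0.8), 1), ((0.5, 0.5), 1)]
    )
    def test_classify_rule_and_tie(self, q, label):
        assert classify(np.array(q)) == label


class TestResNetBlock:
    def test_identity_shortcut_with_zero_weights(self):
        cfg = NetworkConfig(scale=1)
        params = {f"block.{k}": np.zeros(s) for k, s in
                  {"W1": (4, 4), "b1": (4,), "W2": (4, 4), "b2": (4,)}.items()}
        x = np.array([[1.0, -2.0, 3.0, 0.5]])
        out = resnet_block(x, 4, 4, params, prefix="block")
        # identity shortcut survives; final LeakyReLU acts on the input
        assert np.allclose(out, leaky_relu(x))

    def test_linear_shortcut_with_zero_weights(self):
        params = {
            "block.W1": np.zeros((3, 5)),
            "block.b1": np.zeros(5),
            "block.W2": np.zeros((5, 5)),
            "block.b2": np.zeros(5),
            "block.Ws": np.zeros((3, 5)),
            "block.bs": np.zeros(5),
        }
        out = resnet_block(np.ones((2, 3)), 3, 5, params, prefix="block")
        assert np.allclose(out, 0.0)

    def test_residual_decomposition(self, rng):
        """Pre-activation output minus shortcut equals the two-layer branch."""
        n = 6
        params = {
            "block.W1": rng.normal(size=(n, n)),
            "block.b1": rng.normal(size=n),
            "block.W2": rng.normal(size=(n, n)),
            "block.b2": rng.normal(size=n),
        }
        x = np.abs(rng.normal(size=(1, n))) + 1.0  # keep final activation linear
        h = leaky_relu(x @ params["block.W1"] + params["block.b1"])
        branch = h @ params["block.W2"] + params["block.b2"]
        out = resnet_block(x, n, n, params, prefix="block")
        assert np.allclose(out, leaky_relu(branch + x))


class TestEncoders:
    @pytest.mark.parametrize("scale", [1, 2])
    def test_dimension_contracts(self, scale, rng):
        cfg = NetworkConfig(scale=scale)
        params = init_parameters(cfg, rng)
        me = measure_encoder(rng.normal(size=(3, 208)), params, cfg)
        pe = point_encoder(rng.normal(size=(5, 2)), params, cfg)
        assert me.shape == (3, 64 * scale)
        assert pe.shape == (5, 64 * scale)
        q = decode(pe, np.broadcast_to(me[:1], pe.shape), params, cfg)
        assert q.shape == (5, 2)
        assert np.allclose(q.sum(axis=1), 1.0)

    def test_zero_parameters_give_uniform_probability(self):
        cfg = NetworkConfig(scale=1)
        params = zero_parameters(cfg)
        me = measure_encoder(np.ones((1, 208)), params, cfg)
        pe = point_encoder(np.ones((1, 2)), params, cfg)
        assert np.allclose(me, 0.0) and np.allclose(pe, 0.0)
        assert np.allclose(decode(pe, me, params, cfg), 0.5)

    def test_wrong_input_length_raises(self, rng):
        cfg = NetworkConfig(scale=1)
        params = init_parameters(cfg, rng)
        with pytest.raises(ValueError):
            measure_encoder(np.ones((1, 100)), params, cfg)
        with pytest.raises(ValueError):
            point_encoder(np.ones((1, 4)), params, cfg)

    def test_decode_symmetric_in_embeddings(self, rng):
        cfg = NetworkConfig(scale=1)
        params = init_parameters(cfg, rng)
        a = rng.normal(size=(4, 64))
        b = rng.normal(size=(4, 64))
        assert np.allclose(decode(a, b, params, cfg), decode(b, a, params, cfg))


class TestParameterCount:
    @pytest.mark.parametrize("scale", [1, 2, 4])
    def test_closed_form_count(self, scale):
        """Total parameter count follows the block dimension tables."""
        cfg = NetworkConfig(scale=scale)

        def block(i, o):
            n = i * o + o + o * o + o  # two linear layers
            if i != o:
                n += i * o + o  # linear shortcut
            return n

        s = scale
        expected = (
            block(208, 128 * s)
            + 2 * block(128 * s, 128 * s)
            + block(128 * s, 64 * s)
            + 2 * block(64 * s, 64 * s)
            + block(2, 32 * s)
            + block(32 * s, 64 * s)
            + block(64 * s, 32 * s)
            + block(32 * s, 2)
        )
        assert parameter_count(cfg) == expected

    def test_init_matches_manifest(self, rng):
        cfg = NetworkConfig(scale=2)
        params = init_parameters(cfg, rng)
        shapes = parameter_shapes(cfg)
        assert set(params) == set(shapes)
        assert all(params[k].shape == shapes[k] for k in shapes)


class TestPrediction:
    @pytest.fixture()
    def net(self, rng):
        cfg = NetworkConfig(scale=1)
        stats = NormalizationStats(m_min=-0.25, m_max=-0.005)
        return ImplicitNetwork(init_parameters(cfg, rng), cfg, stats)

    def test_amortized_equals_per_point(self, net, rng):
        m = rng.uniform(-0.25, -0.005, 208)
        pts = rng.uniform(-0.5, 0.5, size=(50, 2))
        _, q_batch = net.predict_points(m, pts)
        _, q_single = net.predict_points(m, pts[7:8])
        assert np.allclose(q_batch[7], q_single[0], atol=1e-12)

    def test_batch_order_invariance(self, net, rng):
        m = rng.uniform(-0.25, -0.005, 208)
        pts = rng.uniform(-0.5, 0.5, size=(20, 2))
        perm = rng.permutation(20)
        _, q = net.predict_points(m, pts)
        _, qp = net.predict_points(m, pts[perm])
        assert np.allclose(q[perm], qp, atol=1e-12)

    def test_labels_match_classify(self, net, rng):
        m = rng.uniform(-0.25, -0.005, 208)
        pts = rng.uniform(-0.5, 0.5, size=(30, 2))
        labels, q = net.predict_points(m, pts)
        assert np.array_equal(labels, classify(q))

    def test_roundtrip_serialization(self, net, rng, tmp_path):
        p = tmp_path / "model.npz"
        save_model(p, net)
        loaded = load_model(p)
        m = rng.uniform(-0.25, -0.005, 208)
        pts = rng.uniform(-0.5, 0.5, size=(9, 2))
        _, q1 = net.predict_points(m, pts)
        _, q2 = loaded.predict_points(m, pts)
        assert np.array_equal(q1, q2)
        assert loaded.config == net.config
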