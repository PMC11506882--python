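import math

import numpy as np
import pytest

from cstgat import (
    GATHeadParams,
    GATLayerParams,
    GraphWindow,
    LSTMParams,
    attention_coefficients,
    bilstm_forward,
    cstgat_forward,
    gat_forward,
    init_model_params,
    load_checkpoint,
    lstm_step,
    save_checkpoint,
)
from cstgat.autodiff import Tensor
from cstgat.model import forward_batch, gradient_check


def scalar_lstm_oracle(m_seq, w=0.5, h0=0.0, c0=0.0):
    """Independent pure-python evaluation of the gate equations with all
    weights equal to ``w`` and zero biases, H = D = 1."""
    sig = lambda z: 1.0 / (1.0 + math.exp(-z))
    h, c = h0, c0
    trace = []
    for m in m_seq:
        f = sig(w * m + w * h)
        i = sig(w * m + w * h)
        ctil = math.tanh(w * m + w * h)
        o = sig(w * m + w * h)
        c = f * c + i * ctil
        h = o * math.tanh(c)
        trace.append((h, c))
    return trace


def _scalar_params(w=0.5):
    return LSTMParams(
        *[Tensor(np.full((1, 1), w), requires_grad=True) for _ in range(8)],
        *[Tensor(np.zeros(1), requires_grad=True) for _ in range(4)],
    )


def _head(rng, f, fp, slope=0.2):
    return GATHeadParams(
        W=Tensor(rng.normal(size=(fp, f)), requires_grad=True),
        a=Tensor(rng.normal(size=2 * fp), requires_grad=True),
        leaky_slope=slope,
    )


class TestAttention:
    def test_single_neighbour_gets_full_weight(self, rng):
        head = _head(rng, 3, 2)
        adj = np.eye(2, dtype=int)  # self-loops only
        alpha = attention_coefficients(rng.normal(size=(2, 3)), adj, head)
        assert np.allclose(np.diag(alpha), 1.0)
        assert alpha[0, 1] == 0.0 and alpha[1, 0] == 0.0

    def test_identical_features_give_uniform_rows(self, rng):
        head = _head(rng, 3, 2)
        n = 4
        adj = np.ones((n, n), dtype=int)
        feats = np.tile(rng.normal(size=3), (n, 1))
        alpha = attention_coefficients(feats, adj, head)
        assert np.allclose(alpha, 1.0 / n)

    def test_two_node_hand_computation(self):
        W = np.array([[1.0, 0.0], [0.5, -0.5]])
        a = np.array([1.0, -1.0, 0.5, 2.0])
        head = GATHeadParams(W=Tensor(W), a=Tensor(a), leaky_slope=0.2)
        feats = np.array([[1.0, 0.0], [0.0, 1.0]])
        adj = np.ones((2, 2), dtype=int)
        # hand evaluation: Wv_0 = (1, 0.5), Wv_1 = (0, -0.5)
        def e(vi, vj):
            z = a[0] * vi[0] + a[1] * vi[1] + a[2] * vj[0] + a[3] * vj[1]
            return z if z > 0 else 0.2 * z
        wv = [W @ feats[0], W @ feats[1]]
        expected = np.zeros((2, 2))
        for i in range(2):
            logits = [e(wv[i], wv[j]) for j in range(2)]
            ez = np.exp(logits - max(logits))
            expected[i] = ez / ez.sum()
        alpha = attention_coefficients(feats, adj, head)
        assert np.allclose(alpha, expected, atol=1e-12)

    def test_rows_sum_to_one_on_support(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            adj = (rng.random((n, n)) < 0.4).astype(int)
            np.fill_diagonal(adj, 1)
            head = _head(rng, 5, 3)
            alpha = attention_coefficients(rng.normal(size=(n, 5)), adj, head)
            assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(alpha[adj.T == 0] == 0.0)

    def test_isolated_node_error_names_node(self, rng):
        adj = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 0]])
        head = _head(rng, 2, 2)
        with pytest.raises(ValueError, match="node 2"):
            attention_coefficients(rng.normal(size=(3, 2)), adj, head)


class TestGATForward:
    def test_single_node_self_loop_is_sigma_Wv(self, rng):
        from cstgat.model import _gat_layer

        head = _head(rng, 3, 2)
        # single node with a self-loop: alpha is exactly 1
        layer = GATLayerParams(heads=[head], activation="elu")
        feats = rng.normal(size=(1, 3))
        res = _gat_layer(Tensor(feats), np.eye(1), layer).data
        wv = head.W.data @ feats[0]
        expected = np.where(wv > 0, wv, np.exp(wv) - 1)
        assert np.allclose(res[0], expected, atol=1e-12)

    def test_identical_heads_equal_single_head(self, rng):
        h = _head(rng, 4, 3)
        clone = GATHeadParams(W=Tensor(h.W.data.copy()), a=Tensor(h.a.data.copy()), leaky_slope=0.2)
        feats = rng.normal(size=(3, 4))
        adj = np.ones((3, 3), dtype=int)
        w1 = GraphWindow(node_features=feats, adjacency=adj, label=0)
        single = gat_forward(w1, GATLayerParams(heads=[h]))
        triple = gat_forward(w1, GATLayerParams(heads=[h, clone, clone]))
        assert np.allclose(single, triple, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        heads = [_head(rng, 4, 3) for _ in range(2)]
        layer = GATLayerParams(heads=heads)
        feats = rng.normal(size=(5, 4))
        adj = (rng.random((5, 5)) < 0.5).astype(int)
        np.fill_diagonal(adj, 1)
        perm = rng.permutation(5)
        out = gat_forward(GraphWindow(feats, adj, 0), layer)
        out_p = gat_forward(GraphWindow(feats[perm], adj[np.ix_(perm, perm)], 0), layer)
        assert np.allclose(out_p, out[perm], atol=1e-10)


class TestLSTM:
    def test_zero_weights_zero_state(self):
        p = _scalar_params(w=0.0)
        h, c = lstm_step(np.array([1.0]), np.zeros(1), np.zeros(1), p)
        assert np.allclose(c.data, 0.0) and np.allclose(h.data, 0.0)

    def test_zero_weights_nonzero_cell_gate_algebra(self):
        p = _scalar_params(w=0.0)
        c_prev = np.array([0.8])
        h, c = lstm_step(np.array([1.0]), np.zeros(1), c_prev, p)
        assert np.allclose(c.data, 0.5 * c_prev)
        assert np.allclose(h.data, 0.5 * np.tanh(0.5 * c_prev))

    def test_scalar_hand_oracle_single_step(self):
        (h1, c1), = scalar_lstm_oracle([1.0])
        h, c = lstm_step(np.array([1.0]), np.zeros(1), np.zeros(1), _scalar_params())
        assert h.data[0] == pytest.approx(h1, abs=1e-12)
        assert c.data[0] == pytest.approx(c1, abs=1e-12)
        # frozen oracle values: sigma(0.5)=0.6224593, c~=tanh(0.5)=0.4621172,
        # c_t = 0.2876491, h_t = 0.6224593 * tanh(0.2876491) = 0.1742697
        assert c.data[0] == pytest.approx(0.2876491, abs=1e-5)
        assert h.data[0] == pytest.approx(0.1742697, abs=1e-5)

    def test_three_step_chain_matches_iterated_oracle(self):
        seq = [1.0, -0.5, 2.0]
        trace = scalar_lstm_oracle(seq)
        p = _scalar_params()
        h = np.zeros(1)
        c = np.zeros(1)
        for m, (h_exp, c_exp) in zip(seq, trace):
            ht, ct = lstm_step(np.array([m]), h, c, p)
            h, c = ht.data, ct.data
            assert h[0] == pytest.approx(h_exp, abs=1e-12)
            assert c[0] == pytest.approx(c_exp, abs=1e-12)

    def test_gates_bounded_and_cell_growth_limited(self, rng):
        p = _scalar_params(w=0.9)
        c = np.zeros(1)
        h = np.zeros(1)
        for _ in range(50):
            ht, ct = lstm_step(rng.normal(size=1), h, c, p)
            assert np.all(np.abs(ct.data) <= np.abs(c) + 1.0 + 1e-12)
            h, c = ht.data, ct.data

    def test_bilstm_single_step_concatenates_directions(self, rng):
        p = _scalar_params()
        seq = np.array([[1.0]])
        out = bilstm_forward(seq, p, p)
        h, _ = lstm_step(np.array([1.0]), np.zeros(1), np.zeros(1), p)
        assert np.allclose(out, np.concatenate([h.data, h.data]))

    def test_palindrome_with_shared_params_gives_symmetric_halves(self):
        p = _scalar_params()
        seq = np.array([[1.0], [2.0], [1.0]])
        out = bilstm_forward(seq, p, p)
        assert out[0] == pytest.approx(out[1], abs=1e-12)

    def test_three_step_bilstm_matches_oracle(self):
        p = _scalar_params()
        seq = [0.3, -1.0, 0.7]
        out = bilstm_forward(np.array(seq).reshape(3, 1), p, p)
        fwd = scalar_lstm_oracle(seq)[-1][0]
        bwd = scalar_lstm_oracle(seq[::-1])[-1][0]
        assert out[0] == pytest.approx(fwd, abs=1e-12)
        assert out[1] == pytest.approx(bwd, abs=1e-12)


class TestFullForward:
    def _instance(self, rng, variant="full", pooling="mean"):
        params = init_model_params(
            n_channels=3, feat_per_sub=4, gat_out=5, heads=2, hidden=4,
            variant=variant, pooling=pooling, seed=7,
        )
        feats = rng.normal(size=(3, 8))
        adj = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        return params, GraphWindow(feats, adj, label=1)

    def test_probabilities_valid_and_deterministic(self, rng):
        params, w = self._instance(rng)
        p1 = cstgat_forward(w, 2, params)
        p2 = cstgat_forward(w, 2, params)
        assert np.array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_tied_classifier_rows_give_half_half(self, rng):
        params, w = self._instance(rng)
        params.classifier_W.data[1] = params.classifier_W.data[0]
        params.classifier_b.data[:] = 0.0
        probs = cstgat_forward(w, 2, params)
        assert np.allclose(probs, [0.5, 0.5])

    def test_indivisible_subwindow_split_suggests_valid(self, rng):
        params, w = self._instance(rng)
        with pytest.raises(ValueError, match="divisible|valid S"):
            cstgat_forward(w, 3, params)

    @pytest.mark.parametrize("variant,pooling", [
        ("full", "mean"), ("full", "node_flatten"), ("gat_only", "mean"), ("bilstm_only", "mean"),
    ])
    def test_gradient_check_all_variants(self, rng, variant, pooling):
        params, w = self._instance(rng, variant=variant, pooling=pooling)
        feats = np.stack([w.node_features, rng.normal(size=(3, 8))])
        adj = np.stack([w.adjacency, w.adjacency])
        err = gradient_check(params, feats, adj, np.array([0, 1]), sub_windows=2)
        assert err < 1e-4

    def test_dropout_only_in_train_mode(self, rng):
        params, w = self._instance(rng)
        g = np.random.default_rng(0)
        p_train = cstgat_forward(w, 2, params, train_mode=True, rng=g)
        p_eval = cstgat_forward(w, 2, params, train_mode=False)
        assert not np.allclose(p_train, p_eval)

    def test_checkpoint_round_trip_bit_exact(self, rng, tmp_path):
        params, w = self._instance(rng)
        save_checkpoint(params, tmp_path / "m.h5")
        back = load_checkpoint(tmp_path / "m.h5")
        for a, b in zip(params.tensors(), back.tensors()):
            assert np.array_equal(a.data, b.data)
        assert np.array_equal(cstgat_forward(w, 2, params), cstgat_forward(w, 2, back))
        assert back.variant == params.variant and back.pooling == params.pooling

    def test_batched_forward_matches_single(self, rng):
        params, w = self._instance(rng)
        w2 = GraphWindow(rng.normal(size=(3, 8)), w.adjacency, 0)
        feats = np.stack([w.node_features, w2.node_features])
        adj = np.stack([w.adjacency, w2.adjacency])
        _, probs = forward_batch(feats, adj, params, 2)
        assert np.allclose(probs[0], cstgat_forward(w, 2, params), atol=1e-12)
        assert np.allclose(probs[1], cstgat_forward(w2, 2, params), atol=1e-12)
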