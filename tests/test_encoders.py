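"""Encoder behavior: aggregation correctness, symmetry/invariance
properties, projection-head and classifier contracts."""

import numpy as np
import pytest

from pepclip.autodiff import Tensor
from pepclip.nn import (
    ClassifierHead,
    GraphEncoder,
    ProjectionHead,
    SAGEConv,
    TextEncoder,
    mean_adjacency,
)


def dense_sage_oracle(x, edges, w_self, w_neigh, bias):
    """Independent loop-based computation of one aggregation step."""
    n = len(x)
    neigh = {i: [] for i in range(n)}
    for i, j in edges:
        neigh[i].append(j)
        neigh[j].append(i)
    out = np.zeros((n, w_self.shape[1]))
    for i in range(n):
        mean = (
            np.mean([x[j] for j in neigh[i]], axis=0)
            if neigh[i]
            else np.zeros(x.shape[1])
        )
        out[i] = x[i] @ w_self + mean @ w_neigh + bias
    return np.maximum(out, 0.0)


class TestSAGEConv:
    def test_isolated_node_gets_zero_neighbor_term(self):
        rng = np.random.default_rng(0)
        conv = SAGEConv(3, 4, rng)
        x = np.ones((1, 3))
        out = conv(Tensor(x), mean_adjacency(1, np.empty((0, 2), int))).data
        expected = np.maximum(x @ conv.w_self.data + conv.bias.data, 0.0)
        assert np.allclose(out, expected)

    def test_complete_graph_identical_features_identical_outputs(self):
        rng = np.random.default_rng(1)
        conv = SAGEConv(3, 5, rng)
        n = 6
        edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        x = np.tile([1.0, -2.0, 0.5], (n, 1))
        out = conv(Tensor(x), mean_adjacency(n, edges)).data
        assert np.allclose(out, out[0])

    def test_five_node_graph_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        conv = SAGEConv(4, 3, rng)
        x = rng.normal(size=(5, 4))
        edges = np.array([[0, 1], [1, 2], [2, 3], [0, 4]])
        got = conv(Tensor(x), mean_adjacency(5, edges)).data
        want = dense_sage_oracle(x, edges, conv.w_self.data, conv.w_neigh.data, conv.bias.data)
        assert np.allclose(got, want, atol=1e-6)

    @pytest.mark.parametrize("n", range(1, 9))
    @pytest.mark.parametrize("density", [0.0, 0.3, 0.7, 1.0])
    def test_exhaustive_small_graph_sweep_matches_oracle(self, n, density):
        rng = np.random.default_rng(n * 17 + int(density * 10))
        conv = SAGEConv(3, 3, rng)
        x = rng.normal(size=(n, 3))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        keep = rng.random(len(pairs)) < density
        edges = np.array([p for p, k in zip(pairs, keep) if k]).reshape(-1, 2)
        got = conv(Tensor(x), mean_adjacency(n, edges)).data
        want = dense_sage_oracle(x, edges, conv.w_self.data, conv.w_neigh.data, conv.bias.data)
        assert np.allclose(got, want, atol=1e-6)


class TestGraphEncoder:
    @staticmethod
    def _features(rng, n):
        feats = rng.normal(size=(n, 10))
        feats[:, 3] = 6  # atomic number
        return feats

    def test_empty_graph_is_an_error(self):
        enc = GraphEncoder()
        with pytest.raises(ValueError):
            enc(np.empty((0, 10)), np.empty((0, 2), int))

    def test_permutation_invariant_readout(self):
        rng = np.random.default_rng(3)
        enc = GraphEncoder(hidden_width=8, mlp_widths=(8,), out_width=4, seed=1)
        x = self._features(rng, 7)
        edges = np.array([[0, 1], [2, 3], [4, 5], [5, 6], [1, 4]])
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        x_p = x[perm]
        edges_p = np.array([[inv[i], inv[j]] for i, j in edges])
        out1 = enc(x, edges).data
        out2 = enc(x_p, edges_p).data
        assert np.allclose(out1, out2, atol=1e-6)

    def test_translation_invariant_with_centering(self):
        rng = np.random.default_rng(4)
        enc = GraphEncoder(hidden_width=8, mlp_widths=(8,), out_width=4, seed=2)
        x = self._features(rng, 6)
        shifted = x.copy()
        shifted[:, :3] += np.array([50.0, -20.0, 7.0])
        edges = np.array([[0, 1], [1, 2]])
        assert np.allclose(enc(x, edges).data, enc(shifted, edges).data, atol=1e-10)

    def test_translation_sensitivity_without_centering(self):
        rng = np.random.default_rng(5)
        enc = GraphEncoder(
            hidden_width=8, mlp_widths=(8,), out_width=4, center_coords=False, seed=3
        )
        x = self._features(rng, 6)
        shifted = x.copy()
        shifted[:, :3] += np.array([50.0, -20.0, 7.0])
        edges = np.array([[0, 1], [1, 2]])
        assert not np.allclose(enc(x, edges).data, enc(shifted, edges).data)

    def test_output_is_sigmoid_bounded(self):
        rng = np.random.default_rng(6)
        enc = GraphEncoder(hidden_width=8, mlp_widths=(8,), out_width=4, seed=4)
        out = enc(self._features(rng, 5), np.array([[0, 1]])).data
        assert np.all((out > 0) & (out < 1))

    def test_bias_feature_switch_gives_width_eleven_input(self):
        enc = GraphEncoder(append_bias_feature=True, seed=0)
        prepared = enc.prepare_features(np.zeros((3, 10)))
        assert prepared.shape == (3, 11)
        assert np.all(prepared[:, -1] == 1.0)


class TestTextEncoder:
    @staticmethod
    def _encoder(pooling="first_token"):
        return TextEncoder(
            vocab_size=24, max_length=12, width=16, n_layers=1, n_heads=2,
            pooling=pooling, seed=0,
        )

    def test_deterministic_for_identical_inputs(self):
        enc = self._encoder()
        ids = np.array([[2, 4, 5, 3, 0, 0]])
        mask = np.array([[1, 1, 1, 1, 0, 0]])
        assert np.array_equal(enc(ids, mask).data, enc(ids, mask).data)

    @pytest.mark.parametrize("pooling", ["first_token", "mean"])
    def test_extra_padding_leaves_embedding_unchanged(self, pooling):
        enc = self._encoder(pooling)
        ids = np.array([[2, 4, 5, 6, 3]])
        mask = np.array([[1, 1, 1, 1, 1]])
        padded_ids = np.array([[2, 4, 5, 6, 3, 0, 0, 0]])
        padded_mask = np.array([[1, 1, 1, 1, 1, 0, 0, 0]])
        a = enc(ids, mask).data
        b = enc(padded_ids, padded_mask).data
        assert np.allclose(a, b, atol=1e-5)

    def test_position_sensitivity(self):
        enc = self._encoder()
        mask = np.array([[1, 1, 1, 1]])
        a = enc(np.array([[2, 4, 5, 3]]), mask).data
        b = enc(np.array([[2, 5, 4, 3]]), mask).data
        assert not np.allclose(a, b)

    def test_overlong_input_is_an_error(self):
        enc = self._encoder()
        with pytest.raises(ValueError, match="max_length"):
            enc(np.zeros((1, 13), dtype=int), np.ones((1, 13)))

    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError):
            TextEncoder(vocab_size=24, max_length=8, width=10, n_heads=4)


class TestProjectionHead:
    def test_zero_input_is_deterministic_bias_pattern(self):
        head = ProjectionHead(8, latent_width=6, dropout_rate=0.5, seed=0)
        a = head(Tensor(np.zeros((2, 8)))).data  # no rng -> evaluation mode
        b = head(Tensor(np.zeros((2, 8)))).data
        assert np.array_equal(a, b)
        assert np.allclose(a[0], a[1])

    def test_shared_latent_width_across_modalities(self):
        text_head = ProjectionHead(16, latent_width=128, seed=1)
        graph_head = ProjectionHead(4, latent_width=128, seed=2)
        assert text_head(Tensor(np.ones((3, 16)))).shape == (3, 128)
        assert graph_head(Tensor(np.ones((3, 4)))).shape == (3, 128)

    def test_dropout_only_when_rng_supplied(self):
        head = ProjectionHead(8, latent_width=8, dropout_rate=0.9, seed=3)
        x = Tensor(np.ones((4, 8)))
        eval_out = head(x).data
        train_out = head(x, np.random.default_rng(0)).data
        assert not np.allclose(eval_out, train_out)

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ValueError):
            ProjectionHead(8, dropout_rate=1.0)


class TestClassifierHead:
    def test_zero_weights_give_half(self):
        head = ClassifierHead(5, seed=0)
        head.linear.weight.data[:] = 0.0
        out = head(Tensor(np.ones((3, 5)))).data
        assert np.allclose(out, 0.5)

    def test_probability_monotone_in_logit(self):
        head = ClassifierHead(1, seed=1)
        head.linear.weight.data[:] = 1.0
        xs = np.linspace(-3, 3, 7).reshape(-1, 1)
        probs = head(Tensor(xs)).data.reshape(-1)
        assert np.all(np.diff(probs) > 0)

    def test_output_strictly_inside_unit_interval(self):
        head = ClassifierHead(4, seed=2)
        out = head(Tensor(np.random.default_rng(0).normal(size=(20, 4)) * 10)).data
        assert np.all((out > 0) & (out < 1))
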