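"""GCN and GATv2 layers against dense brute-force oracles."""

import numpy as np
import pytest

from molfuse._tensor import Tensor
from molfuse.exceptions import ShapeError
from molfuse.gnn import (GATv2Layer, GCNLayer, add_self_loops,
                         normalized_adjacency)


def random_undirected_graph(n, rng, p=0.4):
    """Symmetric directed edge list of a random simple graph."""
    src, dst = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                src += [i, j]
                dst += [j, i]
    return np.asarray([src, dst], dtype=np.int64).reshape(2, -1)


def gcn_oracle(H, edge_index, W, b):
    """Dense explicit normalized-adjacency product."""
    n = H.shape[0]
    A = np.zeros((n, n))
    if edge_index.size:
        A[edge_index[1], edge_index[0]] = 1.0
    A += np.eye(n)
    Dinv = np.diag(1.0 / np.sqrt(A.sum(axis=1)))
    return np.maximum(Dinv @ A @ Dinv @ H @ W + b, 0.0)


def gatv2_oracle(H, ei_sl, layer):
    """Per-node explicit softmax attention (loops over neighborhoods)."""
    n, heads, d = H.shape[0], layer.heads, layer.d_out
    Wl, Wr, a, b = (layer.Wl.data, layer.Wr.data, layer.att.data,
                    layer.b.data)
    out = np.zeros((n, heads * d))
    alpha_ref = np.zeros((ei_sl.shape[1], heads))
    for i in range(n):
        in_edges = [k for k in range(ei_sl.shape[1]) if ei_sl[1, k] == i]
        nbrs = [int(ei_sl[0, k]) for k in in_edges]
        for h in range(heads):
            scores = []
            for j in nbrs:
                z = (H[i] @ Wl + H[j] @ Wr).reshape(heads, d)[h]
                z = np.where(z > 0, z, 0.2 * z)
                scores.append(a[h] @ z)
            scores = np.asarray(scores)
            e = np.exp(scores - scores.max())
            alpha = e / e.sum()
            for al, j, k in zip(alpha, nbrs, in_edges):
                out[i, h * d:(h + 1) * d] += al * (H[j] @ Wr).reshape(
                    heads, d)[h]
                alpha_ref[k, h] = al
    return np.maximum(out + b, 0.0), alpha_ref


class TestGCN:
    def test_single_node_identity(self):
        layer = GCNLayer(1, 1, np.random.default_rng(0),
                         activation="identity", dtype=np.float64)
        layer.W.data = np.eye(1)
        layer.b.data = np.zeros(1)
        h = Tensor(np.array([[3.5]]))
        out = layer(h, normalized_adjacency(np.zeros((2, 0), dtype=np.int64),
                                            1))
        np.testing.assert_allclose(out.data, [[3.5]])

    def test_two_node_path_hand_computed(self):
        # A+I on a 2-path has every entry 1; D̃=2I, so Â is all 1/2.
        layer = GCNLayer(1, 1, np.random.default_rng(0),
                         activation="identity", dtype=np.float64)
        layer.W.data = np.eye(1)
        layer.b.data = np.zeros(1)
        ei = np.asarray([[0, 1], [1, 0]])
        out = layer(Tensor(np.array([[1.0], [0.0]])),
                    normalized_adjacency(ei, 2))
        np.testing.assert_allclose(out.data, [[0.5], [0.5]])

    def test_zero_input_zero_preactivation(self):
        layer = GCNLayer(3, 2, np.random.default_rng(1), dtype=np.float64)
        layer.b.data = np.zeros(2)
        ei = np.asarray([[0, 1], [1, 0]])
        out = layer(Tensor(np.zeros((2, 3))), normalized_adjacency(ei, 2))
        np.testing.assert_allclose(out.data, 0.0)

    def test_shape_mismatch_raises(self):
        layer = GCNLayer(3, 2, np.random.default_rng(1))
        with pytest.raises(ShapeError):
            layer(Tensor(np.zeros((2, 5))),
                  normalized_adjacency(np.zeros((2, 0), dtype=np.int64), 2))

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(40):
            n = int(rng.integers(1, 13))
            ei = random_undirected_graph(n, rng)
            H = rng.standard_normal((n, 6))
            layer = GCNLayer(6, 4, np.random.default_rng(trial),
                             dtype=np.float64)
            out = layer(Tensor(H), normalized_adjacency(ei, n)).data
            ref = gcn_oracle(H, ei, layer.W.data, layer.b.data)
            np.testing.assert_allclose(out, ref, atol=1e-10)


class TestGATv2:
    def test_single_node_self_attention_is_one(self):
        layer = GATv2Layer(3, 2, np.random.default_rng(0), dtype=np.float64)
        ei, _ = add_self_loops(np.zeros((2, 0), dtype=np.int64), 1)
        out, alpha = layer(Tensor(np.ones((1, 3))), ei)
        np.testing.assert_allclose(alpha.data, 1.0)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        n = 8
        ei, _ = add_self_loops(random_undirected_graph(n, rng), n)
        layer = GATv2Layer(4, 3, rng, heads=2, dtype=np.float64)
        _, alpha = layer(Tensor(rng.standard_normal((n, 4))), ei)
        sums = np.zeros((n, 2))
        np.add.at(sums, ei[1], alpha.data)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_star_alpha_ranking_matches_raw_scores(self):
        """On a 3-leaf star the center's attention ranking must follow the
        raw pre-softmax scores (softmax is monotone)."""
        rng = np.random.default_rng(5)
        ei = np.asarray([[1, 2, 3, 0, 0, 0], [0, 0, 0, 1, 2, 3]])
        ei, _ = add_self_loops(ei, 4)
        H = rng.standard_normal((4, 3)) * 2
        layer = GATv2Layer(3, 2, rng, dtype=np.float64)
        _, alpha = layer(Tensor(H), ei)
        _, alpha_ref = gatv2_oracle(H, ei, layer)
        center_in = [k for k in range(ei.shape[1]) if ei[1, k] == 0]
        got = np.argsort(alpha.data[center_in, 0])
        ref = np.argsort(alpha_ref[center_in, 0])
        np.testing.assert_array_equal(got, ref)

    def test_matches_brute_force_oracle_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for trial in range(30):
            n = int(rng.integers(1, 13))
            ei, _ = add_self_loops(random_undirected_graph(n, rng), n)
            H = rng.standard_normal((n, 5))
            layer = GATv2Layer(5, 3, np.random.default_rng(trial),
                               heads=int(rng.integers(1, 3)),
                               dtype=np.float64)
            out, alpha = layer(Tensor(H), ei)
            ref, alpha_ref = gatv2_oracle(H, ei, layer)
            np.testing.assert_allclose(out.data, ref, atol=1e-8)
            np.testing.assert_allclose(alpha.data, alpha_ref, atol=1e-8)


class TestLayerProperties:
    @pytest.mark.parametrize("kind", ["gcn", "gatv2"])
    def test_permutation_equivariance(self, kind):
        rng = np.random.default_rng(13)
        n = 7
        ei = random_undirected_graph(n, rng)
        H = rng.standard_normal((n, 4))
        perm = rng.permutation(n)
        ei_p = perm[ei]
        if kind == "gcn":
            layer = GCNLayer(4, 3, np.random.default_rng(1), dtype=np.float64)
            out = layer(Tensor(H), normalized_adjacency(ei, n)).data
            out_p = layer(Tensor(H[np.argsort(perm)]),
                          normalized_adjacency(ei_p, n)).data
        else:
            layer = GATv2Layer(4, 3, np.random.default_rng(1),
                               dtype=np.float64)
            sl, _ = add_self_loops(ei, n)
            sl_p, _ = add_self_loops(ei_p, n)
            out = layer(Tensor(H), sl)[0].data
            out_p = layer(Tensor(H[np.argsort(perm)]), sl_p)[0].data
        # relabeled output at new index perm[i] equals original output at i
        np.testing.assert_allclose(out, out_p[perm], atol=1e-10)

    @pytest.mark.parametrize("kind", ["gcn", "gatv2"])
    def test_disconnected_components_do_not_mix(self, kind):
        """Changing component B's features leaves component A's output
        unchanged after one layer."""
        rng = np.random.default_rng(17)
        ei = np.asarray([[0, 1, 2, 3], [1, 0, 3, 2]])  # edges 0-1 and 2-3
        H1 = rng.standard_normal((4, 3))
        H2 = H1.copy()
        H2[2:] += 5.0
        if kind == "gcn":
            layer = GCNLayer(3, 3, np.random.default_rng(2), dtype=np.float64)
            a_hat = normalized_adjacency(ei, 4)
            o1 = layer(Tensor(H1), a_hat).data
            o2 = layer(Tensor(H2), a_hat).data
        else:
            layer = GATv2Layer(3, 3, np.random.default_rng(2),
                               dtype=np.float64)
            sl, _ = add_self_loops(ei, 4)
            o1 = layer(Tensor(H1), sl)[0].data
            o2 = layer(Tensor(H2), sl)[0].data
        np.testing.assert_allclose(o1[:2], o2[:2])
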