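import numpy as np
import pytest

from dhanmkf.autodiff import Tensor
from dhanmkf.encoders import (
    EncoderConfig,
    forward,
    init_features,
    init_params,
    intra_layer,
)
from dhanmkf.hetgraph import TypedEdges, build_graph


def make_graph(n_c=8, n_d=6, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random((n_c, n_d)) < 0.4).astype(float)
    y[0, 0] = 1  # at least one positive
    s_c = rng.random((n_c, n_c))
    s_c = (s_c + s_c.T) / 2
    np.fill_diagonal(s_c, 1.0)
    s_d = rng.random((n_d, n_d))
    s_d = (s_d + s_d.T) / 2
    np.fill_diagonal(s_d, 1.0)
    graph, _, _ = build_graph(y, s_c, s_d, k_circ="median", k_drug="median", sparsify_k=3)
    return graph, s_c, s_d, y


class TestInitFeatures:
    def test_identity_composition_selects_columns(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        w = Tensor(np.eye(2))
        h0 = init_features(np.eye(3), y, w)
        np.testing.assert_allclose(h0.data, y)

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(1)
        s = rng.random((3, 3))
        y = rng.random((3, 2))
        w = rng.random((2, 2))
        h0 = init_features(s, y, Tensor(w)).data
        expected = np.zeros((3, 2))
        for i in range(3):
            for k in range(2):
                for a in range(3):
                    for b in range(2):
                        expected[i, k] += s[i, a] * y[a, b] * w[b, k]
        np.testing.assert_allclose(h0, expected, atol=1e-12)

    def test_zero_training_matrix_gives_zero_features(self):
        h0 = init_features(np.eye(3), np.zeros((3, 2)), Tensor(np.ones((2, 4))))
        np.testing.assert_array_equal(h0.data, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            init_features(np.eye(3), np.zeros((3, 2)), Tensor(np.ones((3, 4))))


def encoder_setup(heads=1, seed=0, dropout=0.0, **kwargs):
    graph, s_c, s_d, y = make_graph(seed=seed)
    cfg = EncoderConfig(dim=4, heads=heads, dropout=dropout, seed=seed, **kwargs)
    params = init_params(s_c.shape[0], s_d.shape[0], graph, cfg)
    return graph, s_c, s_d, y, cfg, params


class TestAttentionCoefficients:
    def test_all_softmax_groups_sum_to_one(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup(heads=2)
        probe: dict = {}
        forward(graph, s_c, s_d, y, params, cfg, probe=probe)
        checked = 0
        for key, value in probe.items():
            if key[-1] == "weights":
                np.testing.assert_allclose(value.sum(axis=1), 1.0, atol=1e-6)
                checked += 1
            else:
                alpha, seg = value
                for node in np.unique(seg):
                    np.testing.assert_allclose(
                        alpha[seg == node].sum(), 1.0, atol=1e-6
                    )
                    checked += 1
        assert checked > 0

    def test_single_neighbor_gets_full_attention(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        # restrict one relation to a single edge for node 0
        rel = sorted(graph.intra_c)[0]
        graph.intra_c[rel] = (np.array([0]), np.array([1]))
        probe: dict = {}
        feats = Tensor(np.random.default_rng(0).standard_normal((s_c.shape[0], cfg.dim)))
        intra_layer(feats, graph.intra_c, params, "c", 0, cfg, probe=probe)
        alpha, seg = probe[("intra", "c", 0, rel, 0)]
        assert alpha[seg == 0] == pytest.approx(1.0)

    def test_identical_neighbor_features_share_attention(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        rel = sorted(graph.intra_c)[0]
        graph.intra_c = {rel: (np.array([0, 0]), np.array([1, 2]))}
        feats = np.zeros((s_c.shape[0], cfg.dim))
        feats[1] = feats[2] = [1.0, -0.5, 0.25, 2.0]
        probe: dict = {}
        intra_layer(Tensor(feats), graph.intra_c, params, "c", 0, cfg, probe=probe)
        alpha, seg = probe[("intra", "c", 0, rel, 0)]
        np.testing.assert_allclose(alpha[seg == 0], [0.5, 0.5], atol=1e-12)


class TestRelationFusion:
    def test_single_relation_mixture_weight_is_one(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        rel = sorted(graph.intra_c)[0]
        graph.intra_c = {rel: graph.intra_c[rel]}
        probe: dict = {}
        feats = Tensor(np.random.default_rng(1).standard_normal((s_c.shape[0], cfg.dim)))
        intra_layer(feats, graph.intra_c, params, "c", 0, cfg, probe=probe)
        weights = probe[("intra", "c", 0, "weights")]
        np.testing.assert_allclose(weights, 1.0, atol=1e-12)

    def test_global_limit_weights_are_node_independent(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        params["t_raw_c0"].data = np.array([[50.0]])  # sigmoid ~= 1
        probe: dict = {}
        feats = Tensor(np.random.default_rng(2).standard_normal((s_c.shape[0], cfg.dim)))
        intra_layer(feats, graph.intra_c, params, "c", 0, cfg, probe=probe)
        weights = probe[("intra", "c", 0, "weights")]
        np.testing.assert_allclose(weights - weights[0][None, :], 0.0, atol=1e-8)
        # and they equal the softmax of the global relation parameter
        # restricted to the relations present in the graph
        rels = sorted(graph.intra_c)
        beta_g = np.exp(params["betaG_c0"].data[[r - 1 for r in rels], 0])
        beta_g /= beta_g.sum()
        np.testing.assert_allclose(weights[0], beta_g, atol=1e-8)


class TestForward:
    def test_stack_sizes_default_layers(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        stack_c, stack_d = forward(graph, s_c, s_d, y, params, cfg)
        assert len(stack_c) == len(stack_d) == 3
        assert stack_c.kinds == ["init", "intra", "inter"]

    def test_stack_sizes_two_intra_layers(self):
        graph, s_c, s_d, y = make_graph(seed=1)
        cfg = EncoderConfig(dim=4, heads=1, layers_intra=2, dropout=0.0, seed=0)
        params = init_params(s_c.shape[0], s_d.shape[0], graph, cfg)
        stack_c, _ = forward(graph, s_c, s_d, y, params, cfg)
        assert len(stack_c) == 4

    def test_deterministic_without_dropout(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup(seed=5)
        a, _ = forward(graph, s_c, s_d, y, params, cfg)
        b, _ = forward(graph, s_c, s_d, y, params, cfg)
        for x, z in zip(a.layers, b.layers):
            np.testing.assert_array_equal(x.data, z.data)

    def test_permutation_equivariance_circ_side(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup(seed=7)
        stack_c, stack_d = forward(graph, s_c, s_d, y, params, cfg)

        n_c = s_c.shape[0]
        perm = np.random.default_rng(3).permutation(n_c)
        inv = np.argsort(perm)
        y_p = y[perm]
        s_c_p = s_c[np.ix_(perm, perm)]

        graph_p = TypedEdges(
            intra_c={r: (inv[s], inv[d]) for r, (s, d) in graph.intra_c.items()},
            intra_d=graph.intra_d,
            inter={r: (inv[s], d) for r, (s, d) in graph.inter.items()},
        )
        # the drug-side input projection is indexed by circRNA, so its rows
        # must be permuted along with the circRNA axis
        params_p = dict(params)
        params_p["W_intra_d"] = Tensor(params["W_intra_d"].data[perm])
        stack_c_p, stack_d_p = forward(graph_p, s_c_p, s_d, y_p, params_p, cfg)
        for orig, permuted in zip(stack_c.layers, stack_c_p.layers):
            np.testing.assert_allclose(permuted.data, orig.data[perm], atol=1e-10)
        for orig, permuted in zip(stack_d.layers, stack_d_p.layers):
            np.testing.assert_allclose(permuted.data, orig.data, atol=1e-10)

    def test_multi_head_output_is_mean_of_heads(self):
        """With per-head attention vectors copied from h single-head configs,
        the multi-head output equals the average of the single-head outputs."""
        graph, s_c, s_d, y = make_graph(seed=9)
        cfg3 = EncoderConfig(dim=4, heads=3, dropout=0.0, seed=11)
        params3 = init_params(s_c.shape[0], s_d.shape[0], graph, cfg3)
        feats = Tensor(np.random.default_rng(4).standard_normal((s_c.shape[0], 4)))

        multi = intra_layer(feats, graph.intra_c, params3, "c", 0, cfg3)

        cfg1 = EncoderConfig(dim=4, heads=1, dropout=0.0, seed=11)
        singles = []
        for h in range(3):
            params1 = dict(params3)
            for r in graph.intra_c:
                params1[f"a_intra_c0_r{r}_h0"] = params3[f"a_intra_c0_r{r}_h{h}"]
            singles.append(
                intra_layer(feats, graph.intra_c, params1, "c", 0, cfg1).data
            )
        # relation-fusion gates are computed on the head-averaged relation
        # embeddings, so compare the per-relation aggregation stage through
        # the full layer on a single-relation graph (gates then cancel)
        rel = sorted(graph.intra_c)[0]
        single_rel_graph = {rel: graph.intra_c[rel]}
        multi = intra_layer(feats, single_rel_graph, params3, "c", 0, cfg3).data
        singles = []
        for h in range(3):
            params1 = dict(params3)
            params1[f"a_intra_c0_r{rel}_h0"] = params3[f"a_intra_c0_r{rel}_h{h}"]
            singles.append(
                intra_layer(feats, single_rel_graph, params1, "c", 0, cfg1).data
            )
        np.testing.assert_allclose(multi, np.mean(singles, axis=0), atol=1e-10)

    def test_isolated_node_gets_zero_relation_embedding(self):
        graph, s_c, s_d, y, cfg, params = encoder_setup()
        rel = sorted(graph.intra_c)[0]
        # node n_c-1 has no edges under this single-relation graph
        n = s_c.shape[0]
        graph.intra_c = {rel: (np.array([0, 1]), np.array([1, 0]))}
        feats = Tensor(np.random.default_rng(5).standard_normal((n, cfg.dim)))
        out = intra_layer(feats, graph.intra_c, params, "c", 0, cfg)
        np.testing.assert_array_equal(out.data[n - 1], 0.0)
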