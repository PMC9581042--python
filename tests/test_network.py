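"""Network mechanics: embedding, edge-conditioned convolution, forward, ensemble."""

import numpy as np
import pytest

from interpeprank import (
    BinProbabilities,
    EnsembleScorer,
    InterPepRankNet,
    NetworkConfig,
    bin_centers,
    score_from_probs,
)
from interpeprank.graph import DecoyGraph
from interpeprank.network import (
    _backward,
    _code_bits,
    _filter_theta,
    _forward,
    edge_code,
    edge_conditioned_conv,
    embed_aa,
    graphs_to_batch,
    init_params,
)


def tiny_config(**kw):
    defaults = dict(
        n_bins=2, embedding_dim=3, conv_channels=(4, 3), filter_hidden=5,
        dense_sizes=(6, 4),
    )
    defaults.update(kw)
    return NetworkConfig(**defaults)


def pad_graph(g: DecoyGraph, max_nodes: int) -> DecoyGraph:
    n = g.max_nodes
    nf = np.zeros((max_nodes, 64), dtype=g.node_features.dtype)
    nf[:n] = g.node_features
    ef = np.zeros((max_nodes, max_nodes, 4), dtype=g.edge_features.dtype)
    ef[:n, :n] = g.edge_features
    mask = np.zeros(max_nodes, dtype=bool)
    mask[:n] = g.node_mask
    return DecoyGraph(nf, ef, mask, list(g.node_index), g.decoy_id, g.lrmsd, g.lrmsd_norm)


class TestScoreFromProbs:
    def test_single_bin_and_uniform(self):
        assert score_from_probs(np.array([1.0, 0, 0, 0])) == pytest.approx(0.125)
        assert score_from_probs(np.ones(4) / 4) == pytest.approx(0.5)

    def test_two_bin_hand_value(self):
        # 0.25*0.3 + 0.75*0.7 = 0.6
        assert score_from_probs(np.array([0.3, 0.7])) == pytest.approx(0.6)

    def test_bounds_by_bin_centers(self, rng):
        for n in (2, 3, 4):
            centers = bin_centers(n)
            for _ in range(50):
                p = rng.dirichlet(np.ones(n))
                s = score_from_probs(p)
                assert centers[0] - 1e-12 <= s <= centers[-1] + 1e-12

    def test_bin_probabilities_validation(self):
        with pytest.raises(ValueError):
            BinProbabilities(probs=np.array([0.5, 0.1]))
        bp = BinProbabilities(probs=np.array([0.25, 0.75]))
        assert bp.score == pytest.approx(0.25 * 0.25 + 0.75 * 0.75)


class TestEmbedding:
    def test_identical_residues_identical_embeddings(self, rng):
        W = rng.normal(size=(21, 5))
        a = np.zeros(21)
        a[3] = 1.0
        np.testing.assert_array_equal(embed_aa(a, W), embed_aa(a.copy(), W))

    def test_width_arithmetic(self):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(0))
        # first conv consumes embedding_dim + 43 features
        din = cfg.embedding_dim + 43
        assert params["conv0_f2_b"].shape[0] == din * cfg.conv_channels[0]

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            embed_aa(np.zeros(20), rng.normal(size=(21, 4)))


class TestEdgeConditionedConv:
    def test_zero_edges_give_bias_only_output(self):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(1))
        H = np.random.default_rng(2).normal(size=(5, cfg.embedding_dim + 43))
        edges = np.zeros((5, 5, 4), dtype=np.uint8)
        out = edge_conditioned_conv(H, edges, np.ones(5, bool), params)
        expected = np.maximum(params["conv0_bias"], 0.0)
        np.testing.assert_allclose(out, np.tile(expected, (5, 1)), atol=1e-12)

    def test_isolated_components_do_not_interact(self):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(1))
        rng = np.random.default_rng(3)
        H = rng.normal(size=(6, cfg.embedding_dim + 43))
        edges = np.zeros((6, 6, 4), dtype=np.uint8)
        for i in range(6):
            edges[i, i, 0] = edges[i, i, 3] = 1
        edges[0, 1, 2] = edges[1, 0, 2] = edges[0, 1, 3] = edges[1, 0, 3] = 1
        edges[4, 5, 2] = edges[5, 4, 2] = edges[4, 5, 3] = edges[5, 4, 3] = 1
        out1 = edge_conditioned_conv(H, edges, np.ones(6, bool), params)
        H2 = H.copy()
        H2[4:] += 10.0  # perturb the other component
        out2 = edge_conditioned_conv(H2, edges, np.ones(6, bool), params)
        np.testing.assert_allclose(out1[:2], out2[:2], atol=1e-12)

    def test_matches_brute_force_loop_oracle(self):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(4))
        rng = np.random.default_rng(5)
        n, din = 3, cfg.embedding_dim + 43
        H = rng.normal(size=(n, din))
        edges = np.zeros((n, n, 4), dtype=np.uint8)
        for i in range(n):
            edges[i, i, 0] = 1
        edges[0, 1, 1] = edges[1, 0, 1] = 1
        edges[1, 2, 2] = edges[2, 1, 2] = 1
        edges[0, 2, 1] = edges[2, 0, 1] = 1
        edges[:, :, 3] = edges[:, :, :3].max(axis=-1)

        out = edge_conditioned_conv(H, edges, np.ones(n, bool), params)

        # naive per-edge loop: mean over neighbors of Theta(e_ij) x_j + bias
        dout = cfg.conv_channels[0]
        expected = np.zeros((n, dout))
        for i in range(n):
            msgs = []
            for j in range(n):
                if edges[i, j].any():
                    c = int(edge_code(edges[i, j][None, None])[0, 0])
                    _, _, theta = _filter_theta(params, 0, c, din, dout)
                    msgs.append(H[j] @ theta)
            expected[i] = np.maximum(
                np.mean(msgs, axis=0) + params["conv0_bias"], 0.0
            )
        np.testing.assert_allclose(out, expected, atol=1e-10)


class TestForward:
    def test_probs_sum_to_one(self, mini_planted):
        net = InterPepRankNet(conv_channels=(4, 4), embedding_dim=3,
                              dense_sizes=(8, 4), max_epochs=1, batch_size=16, seed=0)
        net.fit(mini_planted.graphs[:8], mini_planted.lrmsd()[:8])
        probs = net.predict_proba(mini_planted.graphs[:8])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_output_invariant_to_padding_amount(self, mini_planted):
        net = InterPepRankNet(conv_channels=(4, 4), embedding_dim=3,
                              dense_sizes=(8, 4), max_epochs=1, batch_size=16, seed=0)
        g = mini_planted.graphs[0]
        net.fit([g], [mini_planted.lrmsd()[0]])
        p100 = net.predict_proba([g])
        p120 = net.predict_proba([pad_graph(g, 120)])
        np.testing.assert_allclose(p100, p120, atol=1e-6)
        assert p100.argmax() == p120.argmax()

    def test_permutation_of_real_nodes_preserves_output(self, mini_planted):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(9))
        g = mini_planted.graphs[0]
        feats, code, mask = graphs_to_batch([g])
        p1, _ = _forward(params, cfg, feats, code, mask)
        n = int(mask.sum())
        perm = np.random.default_rng(10).permutation(n)
        feats2 = feats.copy()
        code2 = code.copy()
        feats2[0, :n] = feats[0, perm]
        code2[0, :n, :n] = code[0][np.ix_(perm, perm)]
        p2, _ = _forward(params, cfg, feats2, code2, mask)
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_gradients_match_finite_differences(self, mini_planted):
        cfg = tiny_config()
        params = init_params(cfg, np.random.default_rng(0))
        feats, code, mask = graphs_to_batch(mini_planted.graphs[:4])
        labels = np.array([0, 1, 0, 1])
        eye = np.eye(2)

        def loss():
            probs, _ = _forward(params, cfg, feats, code, mask)
            return -np.mean(np.log(np.sum(probs * eye[labels], axis=1)))

        probs, cache = _forward(params, cfg, feats, code, mask, need_cache=True)
        grads = _backward(params, cfg, cache, probs, eye[labels])
        check_rng = np.random.default_rng(1)
        eps = 1e-6
        for key in ("embed", "conv0_f2_W", "conv1_f1_W", "dense1_W", "out_b"):
            flat, g = params[key].ravel(), grads[key].ravel()
            for i in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[i]) < 1e-4 * max(1.0, abs(num))


class TestTrainingBehaviour:
    def test_same_seed_reproduces_history(self, mini_planted):
        kw = dict(conv_channels=(6, 6), embedding_dim=4, dense_sizes=(8, 4),
                  max_epochs=3, batch_size=16, seed=5)
        a = InterPepRankNet(**kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        b = InterPepRankNet(**kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        assert a.history_.equals(b.history_)
        for k in a.weights_:
            np.testing.assert_array_equal(a.weights_[k], b.weights_[k])

    def test_zero_learning_rate_leaves_weights_unchanged(self, mini_planted):
        net = InterPepRankNet(conv_channels=(4,), embedding_dim=3, dense_sizes=(6, 4),
                              max_epochs=1, learning_rate=0.0, seed=2)
        cfg = net._config()
        init = init_params(cfg, np.random.default_rng(2))
        net.fit(mini_planted.graphs[:8], mini_planted.lrmsd()[:8])
        for k in init:
            np.testing.assert_allclose(net.weights_[k], init[k], atol=1e-12)

    def test_group_overlap_raises(self, mini_planted):
        net = InterPepRankNet(max_epochs=1)
        with pytest.raises(ValueError, match="overlap"):
            net.fit(
                mini_planted.graphs[:4], mini_planted.lrmsd()[:4],
                validation_data=(mini_planted.graphs[4:6], mini_planted.lrmsd()[4:6]),
                groups=["g1", "g1", "g2", "g2"],
                validation_groups=["g2"],
            )

    def test_overfits_small_planted_set(self):
        # learning-capacity smoke test: a small net must memorize 50 decoys
        from interpeprank import make_planted_dataset
        from interpeprank.training import assign_bin, normalize_lrmsd

        ds = make_planted_dataset(2, 25, seed=31)
        net = InterPepRankNet(conv_channels=(16, 16), embedding_dim=8,
                              dense_sizes=(32, 16), max_epochs=200, batch_size=25,
                              edge_dropout=0.0, seed=3)
        net.fit(ds.graphs, ds.lrmsd())
        pred = net.predict_proba(ds.graphs).argmax(axis=1)
        true = np.array([assign_bin(normalize_lrmsd(l), 2) for l in ds.lrmsd()])
        assert (pred == true).mean() >= 0.99


class TestEnsemble:
    def test_mean_of_member_scores(self, mini_planted):
        kw = dict(conv_channels=(4, 4), embedding_dim=3, dense_sizes=(8, 4),
                  max_epochs=2, batch_size=16)
        m1 = InterPepRankNet(seed=1, **kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        m2 = InterPepRankNet(seed=2, **kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        ens = EnsembleScorer([m1, m2])
        g = mini_planted.graphs[:5]
        np.testing.assert_allclose(
            ens.predict(g), (m1.predict(g) + m2.predict(g)) / 2, atol=1e-12
        )

    def test_single_member_is_identity(self, mini_planted):
        kw = dict(conv_channels=(4,), embedding_dim=3, dense_sizes=(8, 4),
                  max_epochs=2, batch_size=16, seed=1)
        m = InterPepRankNet(**kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        ens = EnsembleScorer([m])
        g = mini_planted.graphs[:5]
        np.testing.assert_allclose(ens.predict(g), m.predict(g), atol=1e-12)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            EnsembleScorer([])

    def test_checkpoint_roundtrip(self, tmp_path, mini_planted):
        kw = dict(conv_channels=(4, 4), embedding_dim=3, dense_sizes=(8, 4),
                  max_epochs=2, batch_size=16, seed=1)
        m = InterPepRankNet(**kw).fit(mini_planted.graphs, mini_planted.lrmsd())
        ens = EnsembleScorer([m])
        ens.save(tmp_path / "model")
        back = EnsembleScorer.load(tmp_path / "model")
        g = mini_planted.graphs[:5]
        np.testing.assert_allclose(back.predict(g), ens.predict(g), atol=1e-12)

    def test_config_roundtrip(self):
        cfg = NetworkConfig(n_bins=3, conv_channels=(8, 8), pooling="max")
        assert NetworkConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError):
            NetworkConfig(n_bins=5)
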