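"""Encoder, losses, gradient reversal, and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiral import integration as integ
from spiral.io_graph import SpatialGraph
from spiral.nn import GradientReversal, gradient_reversal, sigmoid


def _graph(neighbor_lists):
    return SpatialGraph(
        n_nodes=len(neighbor_lists),
        neighbor_lists=[np.array(n, dtype=int) for n in neighbor_lists],
        mode="knn",
        param=len(neighbor_lists[0]) or 1,
    )


def _small_model(M=3, hidden=4, embed=4, noise_dim=2, n_batches=2, seed=0):
    cfg = integ.TrainingConfig(hidden=hidden, embed=embed, noise_dim=noise_dim,
                               disc_hidden=(3, 3), seed=seed)
    return integ.init_model(M, n_batches, cfg)


class TestEncoder:
    def test_zero_weights_give_zero_embedding(self):
        model = _small_model()
        for k in ("enc_W1", "enc_W2"):
            model.params[k][:] = 0.0
        g = _graph([[1], [0]])
        emb = integ.encode(model, [np.ones((2, 3))], [g])
        assert np.all(emb.z == 0)

    def test_two_node_path_manual_forward(self):
        """Hand arithmetic of the aggregate/concat/transform rule on a 2-node path."""
        model = _small_model(M=2, hidden=3, embed=2, noise_dim=1)
        X = np.array([[1.0, 2.0], [3.0, -1.0]])
        g = _graph([[1], [0]])
        W1, W2 = model.params["enc_W1"], model.params["enc_W2"]
        # manual: h_N(i) = mean over neighbours; layer1 ReLU, layer2 linear
        z_manual = np.zeros((2, 2))
        h1 = np.zeros((2, 3))
        for i, j in ((0, 1), (1, 0)):
            h1[i] = np.maximum(np.concatenate([X[i], X[j]]) @ W1, 0.0)
        for i, j in ((0, 1), (1, 0)):
            z_manual[i] = np.concatenate([h1[i], h1[j]]) @ W2
        emb = integ.encode(model, [X], [g])
        np.testing.assert_allclose(emb.z, z_manual, atol=1e-12)

    def test_default_embedding_width(self, tiny_pre):
        model = integ.init_model(len(tiny_pre["samples"][0].gene_names), 2)
        emb = integ.encode(
            model, [s.expr for s in tiny_pre["samples"]], tiny_pre["graphs"]
        )
        assert emb.z.shape[1] == 32
        np.testing.assert_array_equal(
            emb.z, np.hstack([emb.z_noise, emb.z_bio])
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        model = _small_model(M=3)
        X = rng.normal(size=(6, 3))
        g = _graph([[1, 2], [0, 2], [0, 1], [4], [3, 5], [4]])
        emb = integ.encode(model, [X], [g])
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g_perm = _graph([sorted(inv[g.neighbor_lists[perm[i]]]) for i in range(6)])
        emb_perm = integ.encode(model, [X[perm]], [g_perm])
        np.testing.assert_allclose(emb_perm.z, emb.z[perm], atol=1e-12)

    def test_two_hop_locality(self):
        """With two layers, z_i ignores expression beyond graph distance 2."""
        rng = np.random.default_rng(1)
        model = _small_model(M=3)
        X = rng.normal(size=(6, 3))
        chain = _graph([[1], [0, 2], [1, 3], [2, 4], [3, 5], [4]])
        z0 = integ.encode(model, [X], [chain]).z
        X2 = X.copy()
        X2[5] += 10.0  # node 5 is 5 hops from node 0, 3 hops from node 2
        z1 = integ.encode(model, [X2], [chain]).z
        np.testing.assert_allclose(z1[:3], z0[:3], atol=1e-12)
        assert not np.allclose(z1[3:], z0[3:])

    def test_isolated_node_aggregates_itself(self):
        model = _small_model(M=3)
        g = _graph([[1], [0], []])
        emb = integ.encode(model, [np.ones((3, 3))], [g])
        assert np.isfinite(emb.z).all()


class TestWalkPairs:
    def test_one_step_walks_land_on_edges(self):
        g = _graph([[1, 2], [0], [0]])
        pairs = integ.sample_walk_pairs(g, n_walks=4, walk_len=1, seed=0)
        edges = {(0, 1), (1, 0), (0, 2), (2, 0)}
        assert set(map(tuple, pairs.positive_pairs)) <= edges

    def test_seeded_reproducibility(self):
        g = _graph([[1, 2], [0, 2], [0, 1]])
        a = integ.sample_walk_pairs(g, n_walks=2, walk_len=2, seed=42)
        b = integ.sample_walk_pairs(g, n_walks=2, walk_len=2, seed=42)
        np.testing.assert_array_equal(a.positive_pairs, b.positive_pairs)
        np.testing.assert_array_equal(a.negative_pairs, b.negative_pairs)

    def test_visit_frequencies_match_transition_matrix(self):
        """Positive-pair frequencies approach the uniform-neighbour transition law."""
        rng = np.random.default_rng(0)
        n = 20
        lists = [
            sorted(set(rng.choice([j for j in range(n) if j != i], size=4)))
            for i in range(n)
        ]
        sym = [set(l) for l in lists]
        for i, l in enumerate(lists):
            for j in l:
                sym[j].add(i)
        g = _graph([sorted(s) for s in sym])
        counts = np.zeros((n, n))
        for seed in range(300):
            pairs = integ.sample_walk_pairs(g, n_walks=2, walk_len=1, seed=seed)
            for i, j in pairs.positive_pairs:
                counts[i, j] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        expected = np.zeros((n, n))
        for i in range(n):
            expected[i, g.neighbor_lists[i]] = 1.0 / len(g.neighbor_lists[i])
        assert np.abs(freq - expected).max() < 0.08

    def test_negatives_exclude_cooccurrence(self):
        g = _graph([[1], [0, 2], [1]])
        pairs = integ.sample_walk_pairs(g, n_walks=3, walk_len=1, seed=0)
        pos_sets: dict = {}
        for i, j in pairs.positive_pairs:
            pos_sets.setdefault(i, set()).add(j)
        for i, j in pairs.negative_pairs:
            assert j not in pos_sets[i] and j != i


class TestLosses:
    def test_contrastive_closed_form_zero_embeddings(self):
        z = np.zeros((3, 4))
        pairs = integ.WalkPairSet(np.array([[0, 1]]), np.array([[0, 2]]))
        loss = integ.graphsage_loss(z, pairs)
        assert loss == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_contrastive_saturates_at_strong_agreement(self):
        z = np.zeros((2, 3))
        z[0] = z[1] = [30.0, 0, 0]
        loss = integ.graphsage_loss(
            z, integ.WalkPairSet(np.array([[0, 1]]), np.empty((0, 2), dtype=int))
        )
        assert loss < 1e-9

    def test_contrastive_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(5, 3))
        pos = np.array([[0, 1], [2, 3], [1, 4]])
        neg = np.array([[0, 4], [2, 1]])
        expected = 0.0
        for i, j in pos:
            expected += -np.log(1 / (1 + np.exp(-z[i] @ z[j])))
        for i, j in neg:
            expected += -np.log(1 - 1 / (1 + np.exp(-z[i] @ z[j])))
        assert integ.graphsage_loss(z, integ.WalkPairSet(pos, neg)) == pytest.approx(
            expected, rel=1e-10
        )

    def test_decoder_zero_weights_give_half(self):
        model = _small_model()
        for k in ("dec_W1", "dec_b1", "dec_W2", "dec_b2"):
            model.params[k][:] = 0.0
        out = integ.decode(model, np.ones((2, 4)))
        np.testing.assert_allclose(out, 0.5)

    def test_decoder_manual_forward(self):
        model = _small_model(M=2, hidden=3, embed=4)
        z = np.array([[0.5, -1.0, 2.0, 0.1]])
        p = model.params
        hidden = np.maximum(z @ p["dec_W1"] + p["dec_b1"], 0.0)
        logits = hidden @ p["dec_W2"] + p["dec_b2"]
        np.testing.assert_allclose(
            integ.decode(model, z), 1 / (1 + np.exp(-logits)), atol=1e-12
        )

    def test_decoder_mirrors_encoder_dims(self):
        model = integ.init_model(100, 2)
        assert model.params["dec_W1"].shape == (32, 512)
        assert model.params["dec_W2"].shape == (512, 100)

    def test_bce_closed_forms(self):
        M = 7
        x = np.full((3, M), 0.5)
        assert integ.reconstruction_loss(x, x) == pytest.approx(M * np.log(2), abs=1e-6)
        x01 = np.array([[0.0, 1.0, 1.0]])
        xhat = np.array([[1e-9, 1 - 1e-9, 1 - 1e-9]])
        assert integ.reconstruction_loss(xhat, x01) < 1e-6

    def test_bce_matches_scalar_loop(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(3, 4))
        xh = rng.uniform(0.05, 0.95, size=(3, 4))
        expected = 0.0
        for i in range(3):
            for j in range(4):
                expected += -x[i, j] * np.log(xh[i, j]) - (1 - x[i, j]) * np.log(1 - xh[i, j])
        assert integ.reconstruction_loss(xh, x) == pytest.approx(expected / 3, rel=1e-10)

    def test_uniform_head_probabilities_give_log2(self):
        model = _small_model()
        for k in model.params:
            if k.startswith(("disc", "clf")):
                model.params[k][:] = 0.0
        emb = integ.EmbeddingSet(
            np.random.default_rng(0).normal(size=(6, 4)), 2, np.repeat([0, 1], 3)
        )
        l_disc, l_class = integ.batch_head_losses(model, emb, np.repeat([0, 1], 3))
        assert l_disc == pytest.approx(np.log(2), abs=1e-6)
        assert l_class == pytest.approx(np.log(2), abs=1e-6)

    def test_three_batch_softmax_matches_scalar_loop(self):
        model = _small_model(n_batches=3)
        rng = np.random.default_rng(1)
        emb = integ.EmbeddingSet(rng.normal(size=(5, 4)), 2, np.arange(5) % 3)
        y = np.array([0, 1, 2, 0, 1])
        l_disc, l_class = integ.batch_head_losses(model, emb, y)
        p = model.params
        a1 = np.maximum(emb.z_bio @ p["disc_W1"] + p["disc_b1"], 0)
        a2 = np.maximum(a1 @ p["disc_W2"] + p["disc_b2"], 0)
        logits = a2 @ p["disc_W3"] + p["disc_b3"]
        expected = 0.0
        for i in range(5):
            e = np.exp(logits[i] - logits[i].max())
            expected += -np.log(e[y[i]] / e.sum())
        assert l_disc == pytest.approx(expected / 5, rel=1e-9)

    def test_total_loss_arithmetic(self):
        assert integ.total_loss(1, 2, 3, 4, M=10, lambda_=0.5, gamma=2) == pytest.approx(30.5)
        assert integ.total_loss(1.5, 2.0, 9, 9, M=3, lambda_=0, gamma=0) == pytest.approx(7.5)
        with pytest.raises(ValueError):
            integ.total_loss(1, 1, 1, 1, M=5, lambda_=-0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0, 10, allow_nan=False), min_size=4, max_size=4),
        M=st.integers(1, 500),
    )
    def test_total_loss_decomposition(self, vals, M):
        l_gs, l_de, l_disc, l_class = vals
        total = integ.total_loss(l_gs, l_de, l_disc, l_class, M, 1.0, 1.0)
        assert total == pytest.approx(l_gs + l_de * M + l_disc + l_class, rel=1e-12)


class TestGradientReversal:
    def test_forward_is_identity(self):
        v = np.array([1.0, -2.0])
        np.testing.assert_array_equal(gradient_reversal(v), v)

    def test_analytic_negation_quadratic(self):
        """d(sum v^2 after GRL)/dv = -2v."""
        grl = GradientReversal()
        v = np.array([0.3, -1.2, 2.0])
        out = grl(v)
        grad_after = grl.backward(2 * out)
        np.testing.assert_allclose(grad_after, -2 * v)

    def test_discriminator_gradient_equals_negated_finite_difference(self):
        model = _small_model()
        rng = np.random.default_rng(3)
        emb = integ.EmbeddingSet(rng.normal(size=(4, 4)), 2, np.repeat([0, 1], 2))
        y = np.repeat([0, 1], 2)
        d_bio, d_noise = integ.batch_head_input_gradients(model, emb, y, through_grl=True)
        h = 1e-5
        fd = np.zeros_like(emb.z_bio)
        for i in range(emb.z_bio.shape[0]):
            for j in range(emb.z_bio.shape[1]):
                zp, zm = emb.z.copy(), emb.z.copy()
                zp[i, 2 + j] += h
                zm[i, 2 + j] -= h
                lp, _ = integ.batch_head_losses(
                    model, integ.EmbeddingSet(zp, 2, emb.sample_idx), y
                )
                lm, _ = integ.batch_head_losses(
                    model, integ.EmbeddingSet(zm, 2, emb.sample_idx), y
                )
                fd[i, j] = (lp - lm) / (2 * h)
        np.testing.assert_allclose(d_bio, -fd, atol=1e-4)
        # classifier path is not reversed
        fd_n = np.zeros_like(emb.z_noise)
        for i in range(emb.z_noise.shape[0]):
            for j in range(2):
                zp, zm = emb.z.copy(), emb.z.copy()
                zp[i, j] += h
                zm[i, j] -= h
                _, lp = integ.batch_head_losses(
                    model, integ.EmbeddingSet(zp, 2, emb.sample_idx), y
                )
                _, lm = integ.batch_head_losses(
                    model, integ.EmbeddingSet(zm, 2, emb.sample_idx), y
                )
                fd_n[i, j] = (lp - lm) / (2 * h)
        np.testing.assert_allclose(d_noise, fd_n, atol=1e-4)


class TestFit:
    def test_zero_epochs_returns_seeded_initial_model(self, tiny_pre):
        cfg = integ.TrainingConfig(epochs=0, seed=11)
        model, _ = integ.fit(tiny_pre["samples"], tiny_pre["graphs"], cfg)
        ref = integ.init_model(
            len(tiny_pre["samples"][0].gene_names), 2, cfg,
            np.random.default_rng(11),
        )
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], ref.params[k])

    def test_seeded_determinism(self, tiny_pre):
        cfg = integ.TrainingConfig(epochs=3, batch_size=32, seed=7)
        m1, e1 = integ.fit(tiny_pre["samples"], tiny_pre["graphs"], cfg)
        m2, e2 = integ.fit(tiny_pre["samples"], tiny_pre["graphs"], cfg)
        assert m1.history[-1] == m2.history[-1]
        np.testing.assert_array_equal(e1.z, e2.z)

    def test_training_reduces_total_loss(self, tiny_pre):
        cfg = integ.TrainingConfig(epochs=15, batch_size=32, seed=0)
        model, _ = integ.fit(tiny_pre["samples"], tiny_pre["graphs"], cfg)
        assert model.history[-1]["l_total"] < model.history[0]["l_total"]


class TestDownstream:
    def test_corrected_expression_range_and_noise_independence(self, tiny_pre):
        cfg = integ.TrainingConfig(epochs=2, batch_size=32, seed=0)
        model, emb = integ.fit(tiny_pre["samples"], tiny_pre["graphs"], cfg)
        corr = integ.corrected_expression(model, emb)
        assert corr.shape == (emb.n_spots, len(tiny_pre["samples"][0].gene_names))
        assert np.all((corr > 0) & (corr < 1))
        # a decoder blind to the noise columns reconstructs identically
        model.params["dec_W1"][: model.dims.noise_dim, :] = 0.0
        np.testing.assert_allclose(
            integ.corrected_expression(model, emb),
            integ.decode(model, emb),
            atol=1e-12,
        )

    def test_predict_on_training_data_is_identity(self, tiny_pre):
        model, emb = integ.fit(
            tiny_pre["samples"], tiny_pre["graphs"],
            integ.TrainingConfig(epochs=1, batch_size=32, seed=0),
        )
        s = tiny_pre["samples"][0]
        emb_new, _ = integ.predict_unseen(model, s, tiny_pre["graphs"][0])
        n0 = s.n_spots
        np.testing.assert_allclose(emb_new.z, emb.z[:n0], atol=1e-12)

    def test_predict_gene_mismatch_lists_missing(self, tiny_pre):
        model, _ = integ.fit(
            tiny_pre["samples"], tiny_pre["graphs"],
            integ.TrainingConfig(epochs=0, seed=0),
        )
        s = tiny_pre["samples"][0]
        bad = s.subset_spots(np.arange(s.n_spots))
        bad.gene_names = ["missing_" + g for g in s.gene_names]
        bad.expr = s.expr
        with pytest.raises(ValueError, match="lacks"):
            integ.predict_unseen(model, bad, tiny_pre["graphs"][0])
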