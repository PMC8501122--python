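import numpy as np
import pytest

from scgraphae.deep_cluster import (assign_labels, clustering_loss,
                                    init_centroids, soft_assignment,
                                    target_distribution)


def kl_oracle(P, Q):
    """Brute-force double-sum KL divergence."""
    total = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            if P[i, j] > 0:
                total += P[i, j] * np.log(P[i, j] / Q[i, j])
    return total


def random_row_stochastic(rng, n, k):
    M = rng.random((n, k)) + 1e-3
    return M / M.sum(axis=1, keepdims=True)


class TestSoftAssignment:
    def test_single_centroid_column_of_ones(self, rng):
        h = rng.normal(size=(5, 3))
        Q = soft_assignment(h, h[:1])
        np.testing.assert_array_equal(Q, np.ones((5, 1)))

    def test_equidistant_symmetry(self):
        h = np.array([[0.0, 0.0]])
        mu = np.array([[1.0, 0.0], [-1.0, 0.0]])
        np.testing.assert_allclose(soft_assignment(h, mu), [[0.5, 0.5]])

    def test_student_t_hand_value(self):
        # h at centroid 1; distance^2 to centroid 2 is 1 -> q = (2/3, 1/3)
        h = np.array([[0.0]])
        mu = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(soft_assignment(h, mu),
                                   [[2 / 3, 1 / 3]], atol=1e-10)

    def test_row_stochastic_and_monotone_in_distance(self, rng):
        h = rng.normal(size=(20, 4))
        mu = rng.normal(size=(3, 4))
        Q = soft_assignment(h, mu)
        np.testing.assert_allclose(Q.sum(axis=1), 1.0, atol=1e-8)
        d2 = ((h[:, None] - mu[None]) ** 2).sum(-1)
        for i in range(20):
            order = np.argsort(d2[i])
            assert (np.diff(Q[i][order]) <= 1e-12).all()

    def test_empty_centroids_error(self, rng):
        with pytest.raises(ValueError):
            soft_assignment(rng.normal(size=(3, 2)),
                            np.empty((0, 2)))


class TestTargetDistribution:
    def test_one_hot_fixed_point(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_uniform_rows_preserved_when_frequencies_equal(self):
        Q = np.full((2, 2), 0.5)
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-12)

    def test_formula_hand_evaluation(self):
        Q = np.array([[0.8, 0.2], [0.6, 0.4]])
        f = Q.sum(axis=0)
        W = Q ** 2 / f
        expect = W / W.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(target_distribution(Q), expect,
                                   atol=1e-12)

    def test_sharpening_keeps_top_rank(self, rng):
        # equal cluster frequencies: top entry of each row keeps its rank
        base = random_row_stochastic(rng, 30, 4)
        Q = np.vstack([base, base[:, ::-1]])  # symmetrize frequencies
        P = target_distribution(Q)
        assert (np.argmax(P, 1) == np.argmax(Q, 1)).all()

    def test_empty_column_error(self):
        with pytest.raises(ValueError, match="1"):
            target_distribution(np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_row_stochastic_output(self, rng):
        P = target_distribution(random_row_stochastic(rng, 10, 5))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-8)
        assert (P >= 0).all()


class TestClusteringLoss:
    def test_identical_distributions_zero(self, rng):
        Q = random_row_stochastic(rng, 6, 3)
        assert clustering_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_log2_hand_value(self):
        val = clustering_loss(np.array([[1.0, 0.0]]),
                              np.array([[0.5, 0.5]]))
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_bruteforce_oracle_and_nonnegative(self, rng):
        for _ in range(5):
            P = random_row_stochastic(rng, 10, 4)
            Q = random_row_stochastic(rng, 10, 4)
            val = clustering_loss(P, Q)
            assert val == pytest.approx(kl_oracle(P, Q), abs=1e-10)
            assert val >= 0

    def test_infinite_divergence_error(self):
        with pytest.raises(ValueError, match="infinite"):
            clustering_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))


class TestAssignLabels:
    def test_argmax_and_tie_rule(self):
        assert assign_labels(np.array([[0.9, 0.1]]))[0] == 0
        assert assign_labels(np.array([[0.5, 0.5]]))[0] == 0

    def test_row_scaling_invariance(self, rng):
        Q = random_row_stochastic(rng, 8, 3)
        scaled = Q * rng.uniform(0.1, 10, size=(8, 1))
        np.testing.assert_array_equal(assign_labels(Q),
                                      assign_labels(scaled))


class TestInitCentroids:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(50, 2)) * 0.5
        b = rng.normal(size=(50, 2)) * 0.5 + 10.0
        h = np.vstack([a, b])
        labels, cen = init_centroids(h, knn_k=25, seed=0)
        assert cen.shape[0] == 2
        # same partition as the blobs
        assert len(set(labels[:50])) == 1 and len(set(labels[50:])) == 1
        means = np.array([a.mean(0), b.mean(0)])
        d = np.linalg.norm(cen[np.argsort(cen[:, 0])]
                           - means[np.argsort(means[:, 0])], axis=1)
        assert (d < 0.5).all()

    def test_identical_points_single_community(self):
        h = np.ones((10, 3))
        with pytest.warns(UserWarning):
            labels, cen = init_centroids(h)
        assert set(labels) == {0}
        assert cen.shape == (1, 3)

    def test_permutation_gives_same_partition(self, rng):
        from scgraphae.metrics import nmi
        h = np.vstack([rng.normal(size=(30, 3)),
                       rng.normal(size=(30, 3)) + 8])
        perm = rng.permutation(60)
        l1, _ = init_centroids(h, seed=0)
        l2, _ = init_centroids(h[perm], seed=0)
        assert nmi(l1[perm], l2) == pytest.approx(1.0)


class TestAlterTrain:
    def test_recovers_separated_clusters(self, four_cluster_data,
                                         small_train_config):
        from scgraphae import embed_counts, nmi
        m, truth = four_cluster_data
        res = embed_counts(m, config=small_train_config, knn_k=35,
                           n_top_genes=300)
        assert res.cluster_state is not None
        assert nmi(truth, res.cluster_state.labels) >= 0.9

    def test_gamma_zero_is_continued_pretraining(self, rng):
        from scgraphae import ModelConfig, alter_train, pretrain
        from scgraphae.graph_autoencoder import init_params
        X = np.abs(rng.normal(size=(40, 10)))
        A = (rng.random((40, 40)) < 0.2).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        cfg = ModelConfig(latent_dim=3, encoder_hidden_dims=(8,),
                          attention_heads=2, feature_decoder_dims=(4, 5),
                          gamma_weight=0.0, pretrain_epochs=5,
                          alter_iterations=2, inner_epochs=2,
                          loss_reduction="mean", seed=0)
        params, _ = pretrain(X, A, cfg)
        params, state, hist = alter_train(X, A, params, cfg)
        assert state.Q.shape[0] == 40  # Q/P still reported
        np.testing.assert_allclose(state.Q.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(state.P.sum(axis=1), 1.0, atol=1e-8)

    def test_seeded_repeat_identical_labels(self, rng):
        from scgraphae import ModelConfig, alter_train, pretrain
        X = np.abs(rng.normal(size=(40, 10)))
        A = (rng.random((40, 40)) < 0.25).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        cfg = ModelConfig(latent_dim=3, encoder_hidden_dims=(8,),
                          attention_heads=2, feature_decoder_dims=(4, 5),
                          pretrain_epochs=5, alter_iterations=2,
                          inner_epochs=2, loss_reduction="mean", seed=0)
        p1, _ = pretrain(X, A, cfg)
        _, s1, _ = alter_train(X, A, p1, cfg)
        p2, _ = pretrain(X, A, cfg)
        _, s2, _ = alter_train(X, A, p2, cfg)
        np.testing.assert_array_equal(s1.labels, s2.labels)
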