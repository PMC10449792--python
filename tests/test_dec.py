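import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from synspan import SynTofDEC, TrainConfig, nmi, soft_assign, target_distribution
from synspan.dec import elbow_from_sse


def brute_force_target(Q):
    """Independent oracle: direct q^2/f computation, row by row."""
    Q = np.asarray(Q, dtype=float)
    f = [sum(Q[i][j] for i in range(len(Q))) for j in range(Q.shape[1])]
    P = np.zeros_like(Q)
    for i in range(len(Q)):
        raw = [Q[i][j] ** 2 / f[j] for j in range(Q.shape[1])]
        P[i] = np.array(raw) / sum(raw)
    return P


class TestSoftAssign:
    def test_far_center_limit(self):
        q = soft_assign(np.array([[0.0, 0.0]]),
                        np.array([[0.0, 0.0], [1e6, 0.0]]), alpha=1.0)
        assert q[0, 0] > 1 - 1e-9 and q[0, 1] < 1e-9

    def test_equidistant_symmetry(self):
        q = soft_assign(np.array([[0.0]]), np.array([[-1.0], [1.0]]), alpha=1.0)
        np.testing.assert_allclose(q[0], [0.5, 0.5], atol=1e-12)

    def test_alpha_one_closed_form(self):
        # distances 1 and sqrt(3): (1+1)^-1 = 0.5, (1+3)^-1 = 0.25 -> (2/3, 1/3)
        q = soft_assign(np.array([[0.0, 0.0]]),
                        np.array([[1.0, 0.0], [np.sqrt(3), 0.0]]), alpha=1.0)
        np.testing.assert_allclose(q[0], [2 / 3, 1 / 3], atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(20, 4))
        mu = rng.normal(size=(5, 4))
        q = soft_assign(z, mu, alpha=1.0)
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)


class TestTargetDistribution:
    def test_symmetry_single_event(self):
        np.testing.assert_allclose(
            target_distribution(np.array([[0.5, 0.5]]))[0], [0.5, 0.5], atol=1e-15
        )

    def test_one_hot_fixed_point(self):
        Q = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(target_distribution(Q), Q, atol=1e-15)

    def test_matches_brute_force_worked_example(self):
        Q = np.array([[0.8, 0.2], [0.4, 0.6]])
        P = target_distribution(Q)
        np.testing.assert_allclose(P, brute_force_target(Q), atol=1e-12)
        np.testing.assert_allclose(P, [[0.914286, 0.085714], [0.228571, 0.771429]],
                                   atol=1e-6)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        Q = rng.dirichlet(np.ones(4), size=15)
        P = target_distribution(Q)
        np.testing.assert_allclose(P, brute_force_target(Q), atol=1e-12)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            target_distribution(np.empty((0, 2)))


class TestPretrain:
    def test_memorizes_constant_input(self):
        X = np.tile([1.0, -0.5, 2.0, 0.0], (256, 1))
        cfg = TrainConfig(latent_dim=2, hidden_layers=(8,), batch_size=64,
                          max_epochs_pretrain=200, patience=200)
        model = SynTofDEC(X, cfg)
        pre = model.pretrain(seed=0)
        assert pre.loss_history[-1] < 1e-3

    def test_blob_latent_separates(self, blobs_3, fast_train_config):
        X, y = blobs_3
        model = SynTofDEC(X, fast_train_config)
        pre = model.pretrain(seed=0)
        Z = pre.encode(model.X)
        labels = KMeans(3, n_init=10, random_state=0).fit_predict(Z)
        assert adjusted_rand_score(y, labels) >= 0.9

    def test_deterministic_loss(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        model = SynTofDEC(X, fast_train_config)
        a = model.pretrain(seed=4).loss_history
        b = model.pretrain(seed=4).loss_history
        assert a == b


class TestFinetune:
    def test_gamma_zero_frozen_equals_kmeans(self, blobs_3):
        """With no clustering loss and frozen weights, labels are exactly K-means."""
        X, _ = blobs_3
        cfg = TrainConfig(latent_dim=4, hidden_layers=(16, 8), batch_size=256,
                          max_epochs_pretrain=20, gamma=0.0, max_epochs_finetune=0)
        model = SynTofDEC(X, cfg)
        pre = model.pretrain(seed=1)
        run = model.finetune(pre, k=3, seed=1)
        Z = pre.encode(model.X)
        km = model._kmeans(Z.astype(np.float64), 3, seed=1)
        np.testing.assert_array_equal(run.labels, km.labels_)

    def test_kl_does_not_increase(self):
        # five overlapping blobs: assignments start soft, so the clustering
        # loss has room to sharpen them; gamma=1 so the KL term, not the
        # reconstruction, dominates what fine-tuning optimises
        rng = np.random.default_rng(3)
        centers = rng.normal(scale=3.0, size=(5, 8))
        X = np.vstack([rng.normal(c, 1.0, size=(300, 8)) for c in centers])
        cfg = TrainConfig(latent_dim=4, hidden_layers=(16, 8), batch_size=256,
                          max_epochs_pretrain=30, max_epochs_finetune=15, gamma=1.0)
        model = SynTofDEC(X, cfg)
        run = model.finetune(model.pretrain(seed=0), k=5, seed=0)
        assert run.kl_final <= run.kl_initial + 1e-9

    def test_q_rows_sum_to_one(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        model = SynTofDEC(X, fast_train_config)
        run = model.finetune(model.pretrain(seed=0), k=3, seed=0)
        np.testing.assert_allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)

    def test_k_below_two_rejected(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        model = SynTofDEC(X, fast_train_config)
        with pytest.raises(ValueError):
            model.finetune(model.pretrain(seed=0), k=1)


class TestElbow:
    def test_three_blobs_pick_three(self, blobs_3):
        X, _ = blobs_3
        sse = [float(KMeans(k, n_init=10, random_state=0).fit(X).inertia_)
               for k in range(2, 9)]
        k, _, has_elbow = elbow_from_sse(range(2, 9), sse)
        assert has_elbow and k == 3

    def test_single_gaussian_no_elbow(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1500, 8))
        sse = [float(KMeans(k, n_init=10, random_state=0).fit(X).inertia_)
               for k in range(2, 9)]
        with pytest.warns(UserWarning, match="no elbow"):
            k, _, has_elbow = elbow_from_sse(range(2, 9), sse)
        assert not has_elbow and k == 2

    def test_short_range_rejected(self):
        with pytest.raises(ValueError):
            elbow_from_sse([2, 3], [5.0, 4.0])

    def test_select_k_on_planted_data(self, small_balanced):
        # full-width encoder, shortened schedule: the 16 planted clusters
        # put the elbow at k=16
        cfg = TrainConfig(max_epochs_pretrain=40, n_runs=1)
        model = SynTofDEC(small_balanced, cfg)
        sel = model.select_k(k_range=range(10, 23), seed=0)
        assert sel.has_elbow and sel.k == 16


class TestEnsemble:
    def test_singleton_ensemble_equals_single_run(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        model = SynTofDEC(X, fast_train_config)
        runset, runs = model.run_ensemble(3, seeds=[5])
        single = model.fit_single(3, seed=5)
        np.testing.assert_array_equal(runset.labelings[0], single.labels)

    def test_runs_agree_on_easy_data(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        model = SynTofDEC(X, fast_train_config)
        runset, _ = model.run_ensemble(3, seeds=[0, 1, 2])
        for i in range(3):
            for j in range(i + 1, 3):
                assert nmi(runset.labelings[i], runset.labelings[j]) >= 0.9

    def test_duplicate_seeds_rejected(self, blobs_3, fast_train_config):
        X, _ = blobs_3
        with pytest.raises(ValueError):
            SynTofDEC(X, fast_train_config).run_ensemble(3, seeds=[1, 1])

    def test_fit_deterministic(self, blobs_3, fast_train_config):
        X, y = blobs_3
        a = SynTofDEC(X, fast_train_config).fit(k=3, seed=2, n_runs=2)
        b = SynTofDEC(X, fast_train_config).fit(k=3, seed=2, n_runs=2)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert adjusted_rand_score(y, a.labels) >= 0.9
        assert "Deep embedded clustering" in a.summary()
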