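import numpy as np
import pytest

from eegcl import (
    ClusterResult,
    ConsciousnessTrace,
    FeatureMatrix,
    ensemble_average,
    fcm,
    gmm_em,
    label_conscious_cluster,
    normalize_features,
)

TWO_BLOBS = np.array([0.00, 0.01, 0.02, 1.00, 1.01, 1.02])


def fcm_fixed_point_oracle(x, m=2.0, tol=1e-12, max_iter=2000):
    """Direct fixed-point iteration of the membership/centroid updates.

    Written independently of the library routine: starts from a
    deterministic near-hard assignment and alternates the two closed-form
    updates until the centroids stop moving.
    """
    x = x[:, None]
    u = np.array([[0.9, 0.1]] * 3 + [[0.1, 0.9]] * 3, dtype=float)
    centroids = None
    for _ in range(max_iter):
        um = u**m
        new_c = (um.T @ x) / um.sum(axis=0)[:, None]
        d = np.abs(x - new_c.T)
        with np.errstate(divide="ignore"):
            inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        if centroids is not None and np.abs(new_c - centroids).max() < tol:
            break
        centroids = new_c
    return np.sort(centroids.ravel()), u


class TestNormalizeFeatures:
    def _fm(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            values=values,
            timestamps=np.arange(values.shape[0], dtype=float),
            feature_names=tuple(f"f{i}" for i in range(values.shape[1])),
        )

    def test_minmax_definition(self):
        out = normalize_features(self._fm([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.values.ravel(), [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_interval_column(self):
        fm = self._fm([[0.0], [0.25], [1.0]])
        out = normalize_features(fm)
        assert np.allclose(out.values, fm.values)

    def test_nan_rows_excluded_and_preserved(self):
        out = normalize_features(self._fm([[1.0], [2.0], [np.nan], [3.0]]))
        assert np.isnan(out.values[2, 0])
        assert np.allclose(out.values[[0, 1, 3], 0], [0.0, 0.5, 1.0])

    def test_constant_column_becomes_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_features(self._fm([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.allclose(out.values[:, 0], 0.5)


class TestFCM:
    def test_two_blob_centroids_and_memberships(self):
        res = fcm(TWO_BLOBS, seed=0)
        centroids = np.sort(res.centroids.ravel())
        assert abs(centroids[0] - 0.01) < 0.05
        assert abs(centroids[1] - 1.01) < 0.05
        own = res.memberships.max(axis=1)
        assert (own > 0.95).all()

    def test_matches_fixed_point_oracle(self):
        res = fcm(TWO_BLOBS, seed=0)
        oracle_c, _ = fcm_fixed_point_oracle(TWO_BLOBS)
        assert np.allclose(np.sort(res.centroids.ravel()), oracle_c, atol=1e-6)

    def test_membership_rows_sum_to_one(self, rng):
        res = fcm(rng.random((50, 3)), seed=1)
        assert np.abs(res.memberships.sum(axis=1) - 1.0).max() < 1e-12

    def test_point_at_centroid_gets_full_membership(self):
        # two exact duplicates force a centroid onto the data point
        data = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        res = fcm(data, seed=0)
        assert np.isclose(res.memberships.max(axis=1), 1.0).all()

    def test_objective_nonincreasing(self, rng):
        res = fcm(rng.random((80, 2)), seed=2)
        assert (np.diff(res.objective_trace) <= 1e-9).all()

    def test_near_hard_limit_matches_nearest_centroid(self, rng):
        data = np.concatenate([rng.normal(0, 0.05, 40), rng.normal(1, 0.05, 40)])
        res = fcm(data, m=1.05, seed=0)
        hard = res.memberships.max(axis=1)
        assert (hard > 0.99).all()
        # each point's top cluster is its nearest centroid
        d = np.abs(data[:, None] - res.centroids.ravel()[None, :])
        assert np.array_equal(res.memberships.argmax(1), d.argmin(1))

    def test_row_permutation_gives_permuted_memberships(self):
        res = fcm(TWO_BLOBS, seed=0)
        perm = np.array([3, 1, 5, 0, 2, 4])
        res_p = fcm(TWO_BLOBS[perm], seed=0)
        # same converged solution up to cluster order
        order = np.argsort(res.centroids.ravel())
        order_p = np.argsort(res_p.centroids.ravel())
        assert np.allclose(
            res.memberships[perm][:, order], res_p.memberships[:, order_p], atol=1e-6
        )

    def test_nan_rows_excluded(self):
        data = np.array([[0.0], [0.01], [np.nan], [1.0], [1.01]])
        res = fcm(data, seed=0)
        assert np.isnan(res.memberships[2]).all()
        assert np.isfinite(res.memberships[[0, 1, 3, 4]]).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fcm(np.array([1.0, 1.0, 1.0]), seed=0)
        with pytest.raises(ValueError):
            fcm(TWO_BLOBS, m=1.0, seed=0)


class TestGMM:
    def test_recovers_simulated_means_and_weights(self):
        r = np.random.default_rng(3)
        data = np.concatenate([r.normal(0, 1, 500), r.normal(5, 1, 500)])
        res = gmm_em(data, seed=0)
        means = np.sort(res.centroids.ravel())
        assert abs(means[0] - 0.0) < 0.2
        assert abs(means[1] - 5.0) < 0.2
        assert np.abs(res.weights - 0.5).max() < 0.05

    def test_posterior_rows_sum_to_one(self, rng):
        res = gmm_em(rng.random((60, 2)), seed=1)
        assert np.abs(res.memberships.sum(axis=1) - 1.0).max() < 1e-12

    def test_log_likelihood_nondecreasing(self, rng):
        res = gmm_em(rng.random((100, 2)), seed=2)
        assert (np.diff(res.objective_trace) >= -1e-8).all()

    def test_single_component_degenerate(self, rng):
        data = rng.random(40)
        res = gmm_em(data, n_clusters=1, seed=0)
        assert np.allclose(res.memberships, 1.0)
        assert res.centroids.ravel()[0] == pytest.approx(data.mean(), abs=1e-6)


class TestLabeling:
    def _result(self, c0, c1):
        c = np.array([c0, c1], dtype=float)
        return ClusterResult(
            memberships=np.ones((1, 2)) / 2,
            centroids=c,
            method="FCM",
            objective_trace=np.array([0.0]),
        )

    def test_dominant_centroid_is_conscious(self):
        res = self._result([0.2] * 7, [0.8] * 7)
        assert label_conscious_cluster(res) == 1

    def test_majority_of_coordinates(self):
        c0 = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1]  # higher in 4 of 7
        c1 = [0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9]
        assert label_conscious_cluster(self._result(c0, c1)) == 0

    def test_tie_broken_by_sef95(self):
        # 3-3 split with one equal coordinate; cluster 0 higher on sef95
        c0 = [0.9, 0.9, 0.8, 0.5, 0.1, 0.1, 0.1]
        c1 = [0.1, 0.1, 0.2, 0.5, 0.9, 0.9, 0.9]
        assert label_conscious_cluster(self._result(c0, c1)) == 0

    def test_full_tie_falls_back_to_centroid_mean(self):
        c0 = [0.6] * 7
        c1 = [0.6] * 7
        assert label_conscious_cluster(self._result(c0, c1)) == 0


class TestEnsemble:
    def _trace(self, values):
        values = np.asarray(values, dtype=float)
        return ConsciousnessTrace(values, np.arange(values.size, dtype=float))

    def test_plain_mean(self):
        out = ensemble_average(self._trace([0.2, 1.0]), self._trace([0.8, 1.0]))
        assert np.allclose(out.p_conscious, [0.5, 1.0])

    def test_idempotent_on_equal_traces(self):
        t = self._trace([0.1, 0.9, 0.4])
        assert np.allclose(ensemble_average(t, t).p_conscious, t.p_conscious)

    def test_misaligned_traces_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average(self._trace([0.1, 0.2]), self._trace([0.1]))
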