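"""Gaussian mixture EM: closed forms, recovery, invariants, reference oracle."""

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture as SkGMM

from cardioclust.mixture import (
    GaussianMixture,
    bic,
    fit_gmm,
    n_mixture_params,
    predict_clusters,
)


def _two_blobs(rng, n=400, d=2, sep=10.0):
    X = rng.normal(size=(n, d))
    X[n // 2 :] += sep
    return X


class TestParamCounts:
    @pytest.mark.parametrize(
        "k,d,cov,expect",
        [
            (9, 8, "full", 8 + 72 + 324),   # 404
            (9, 8, "tied", 8 + 72 + 36),
            (9, 8, "diag", 8 + 72 + 72),
            (1, 1, "full", 2),
            (1, 1, "diag", 2),
        ],
    )
    def test_parameter_count_formula(self, k, d, cov, expect):
        assert n_mixture_params(k, d, cov) == expect


class TestClosedForms:
    def test_k1_full_matches_sample_moments(self, rng):
        X = rng.normal(size=(200, 3)) @ np.diag([1.0, 2.0, 0.5]) + [1, 2, 3]
        res = fit_gmm(X, k=1, cov_type="full", seed=0, n_init=1, standardize=False)
        np.testing.assert_allclose(res.means_[0], X.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(X.T, bias=True)
        np.testing.assert_allclose(
            res.covariances_[0], ml_cov + 1e-6 * np.eye(3), atol=1e-6
        )

    def test_k1_d1_bic_hand_computed(self):
        # three points {0, 1, 2}: mean 1, ML var 2/3 (+reg); logL by hand
        x = np.array([[0.0], [1.0], [2.0]])
        res = fit_gmm(x, k=1, cov_type="full", seed=0, n_init=1,
                      standardize=False, reg_covar=0.0)
        var = 2.0 / 3.0
        ll = sum(
            -0.5 * (np.log(2 * np.pi * var) + (xi - 1.0) ** 2 / var) for xi in [0, 1, 2]
        )
        assert res.loglik_ == pytest.approx(float(ll), abs=1e-8)
        assert res.bic() == pytest.approx(-2 * float(ll) + 2 * np.log(3), abs=1e-8)


class TestFitting:
    def test_two_cluster_parameter_recovery(self, rng):
        X = _two_blobs(rng)
        res = fit_gmm(X, k=2, cov_type="full", seed=1, n_init=5)
        means = res.means_[np.argsort(res.means_[:, 0])]
        np.testing.assert_allclose(means[0], [0, 0], atol=0.5)
        np.testing.assert_allclose(means[1], [10, 10], atol=0.5)
        np.testing.assert_allclose(np.sort(res.weights_), [0.5, 0.5], atol=0.05)

    def test_loglik_trace_monotone(self, rng):
        X = rng.normal(size=(300, 3))
        X[:100] += 3
        for cov in ("tied", "diag", "full"):
            res = fit_gmm(X, k=3, cov_type=cov, seed=2, n_init=2)
            diffs = np.diff(res.loglik_trace)
            assert diffs.min() > -1e-8

    def test_weights_simplex_and_responsibilities_normalized(self, rng):
        X = _two_blobs(rng)
        res = fit_gmm(X, k=3, cov_type="diag", seed=3, n_init=2)
        assert res.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert (res.weights_ > 0).all()
        labels, resp = predict_clusters(res)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-9)
        assert (labels == np.argmax(resp, axis=1)).all()

    def test_isolated_component_dominance(self, rng):
        X = np.vstack([rng.normal(size=(200, 2)), rng.normal(size=(50, 2)) + 50])
        res = fit_gmm(X, k=2, cov_type="full", seed=4, n_init=4)
        far = res.predict(np.array([[50.0, 50.0]]))
        resp = res.predict_proba(np.array([[50.0, 50.0]]))
        assert resp[0, far[0]] > 0.999

    def test_assignment_permutation_invariance(self, rng):
        X = _two_blobs(rng, n=200)
        res = fit_gmm(X, k=2, cov_type="full", seed=5, n_init=3)
        labels = res.predict(X)
        perm = rng.permutation(len(X))
        labels_perm = res.predict(X[perm])
        assert (labels_perm == labels[perm]).all()

    def test_covariance_eigenvalue_floor(self, rng):
        # rank-deficient data: all points on a line
        t = rng.normal(size=150)
        X = np.column_stack([t, 2 * t])
        res = fit_gmm(X, k=2, cov_type="full", seed=6, n_init=2, standardize=False)
        for c in res.covariances_:
            assert np.linalg.eigvalsh(c).min() >= 1e-6 * (1 - 1e-9)

    def test_empty_component_reseeded_not_crash(self, rng):
        # k close to n with tight duplicated points provokes empty components
        X = np.repeat(rng.normal(size=(6, 2)), 3, axis=0)
        res = fit_gmm(X, k=5, cov_type="diag", seed=7, n_init=2)
        assert res.weights_.shape == (5,)

    def test_input_validation(self, rng):
        X = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            GaussianMixture(X, n_components=0)
        with pytest.raises(ValueError):
            GaussianMixture(X, n_components=25)
        with pytest.raises(ValueError):
            GaussianMixture(X, n_components=2, cov_type="spherical")
        with pytest.raises(ValueError):
            GaussianMixture(np.full((20, 2), np.nan), n_components=2)


class TestBICBehaviour:
    def test_bic_consistency_single_gaussian(self, rng):
        # on single-Gaussian data BIC must prefer k=1 over k=5 in >= 19/20 seeds
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(2000, 2))
            b1 = fit_gmm(X, k=1, cov_type="full", seed=seed, n_init=1).bic()
            b5 = fit_gmm(X, k=5, cov_type="full", seed=seed, n_init=2,
                         max_iter=100).bic()
            wins += b1 < b5
        assert wins >= 19

    def test_affine_rescaling_shifts_bic_by_constant(self, rng):
        X = _two_blobs(rng, n=300, d=3)
        Y = X.copy()
        Y[:, 0] *= 10.0
        res_x = fit_gmm(X, k=2, cov_type="full", seed=8, n_init=4)
        res_y = fit_gmm(Y, k=2, cov_type="full", seed=8, n_init=4)
        # assignments unchanged, BIC shifted by exactly 2n log 10
        assert (res_x.predict(X) == res_y.predict(Y)).mean() > 0.999
        shift = res_y.bic() - res_x.bic()
        assert shift == pytest.approx(2 * len(X) * np.log(10.0), rel=1e-4)


class TestReferenceOracle:
    def test_final_loglik_matches_sklearn(self, rng):
        """Best-restart log-likelihood within 1e-3 per case of scikit-learn
        run with matched settings on small random mixtures."""
        for i in range(10):
            r = np.random.default_rng(100 + i)
            n = int(r.integers(120, 300))
            d = int(r.integers(2, 5))
            k = int(r.integers(1, 4))
            centers = r.normal(scale=6.0, size=(k, d))
            X = np.vstack([r.normal(size=(n // k + 1, d)) + c for c in centers])[:n]
            cov = ("tied", "diag", "full")[i % 3]
            ours = fit_gmm(X, k=k, cov_type=cov, seed=i, n_init=6,
                           tol=1e-4, standardize=False)
            sk = SkGMM(
                n_components=k, covariance_type=cov, n_init=6, tol=1e-4,
                reg_covar=1e-6, max_iter=200, random_state=i,
            ).fit(X)
            ours_per_case = ours.loglik_ / n
            sk_per_case = sk.score(X)
            assert ours_per_case == pytest.approx(sk_per_case, abs=1e-3)
            # identical BIC convention
            assert bic(ours) == pytest.approx(
                sk.bic(X) + 2 * (sk.score(X) * n - ours.loglik_), abs=1e-6
            )
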