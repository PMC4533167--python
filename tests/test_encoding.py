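import numpy as np
import pytest
from scipy.stats import norm

import fvstage as fv
from fvstage.encoding import mean_log_likelihood
from tests.conftest import fv_finite_difference, random_gmm


class TestPCAWhitener:
    def test_whitens_anisotropic_gaussian(self, rng):
        cov = np.array([[9.0, 0.8 * 3 * 1], [0.8 * 3 * 1, 1.0]])
        X = rng.multivariate_normal([1.0, -2.0], cov, size=2000)
        w = fv.fit_pca_whitener(X, d=2)
        Y = w.transform(X)
        np.testing.assert_allclose(Y.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(np.cov(Y.T), np.eye(2), atol=1e-6)

    def test_already_white_data_gives_orthonormal_basis(self, rng):
        X = rng.normal(size=(500, 3))
        white = fv.fit_pca_whitener(X, 3).transform(X)  # exactly unit covariance
        w2 = fv.fit_pca_whitener(white, 3)
        np.testing.assert_allclose(w2.basis.T @ w2.basis, np.eye(3), atol=1e-6)

    def test_rank_deficient_data_reduces_dim_with_warning(self, rng):
        direction = np.array([1.0, 2.0])
        X = rng.normal(size=(100, 1)) * direction
        with pytest.warns(UserWarning, match="rank"):
            w = fv.fit_pca_whitener(X, 2)
        assert w.output_dim == 1

    def test_target_dim_exceeding_input_rejected(self, rng):
        with pytest.raises(ValueError, match="dim"):
            fv.fit_pca_whitener(rng.normal(size=(50, 3)), 4)


class TestGMMFit:
    def test_single_component_closed_form(self, rng):
        X = rng.normal(2.0, 1.5, size=(200, 2))
        g = fv.fit_gmm_em(X, K=1, seed=0)
        np.testing.assert_allclose(g.weights, [1.0])
        np.testing.assert_allclose(g.means[0], X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(g.variances[0], X.var(axis=0), atol=1e-12)

    def test_recovers_separated_components(self, rng):
        X = np.vstack(
            [rng.normal((-5, 0), 1, (1000, 2)), rng.normal((5, 0), 1, (1000, 2))]
        )
        g = fv.fit_gmm_em(X, K=2, seed=1)
        order = np.argsort(g.means[:, 0])
        np.testing.assert_allclose(
            g.means[order], [[-5, 0], [5, 0]], atol=0.2
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_log_likelihood_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 3)) * rng.uniform(0.5, 2, 3)
        g = fv.fit_gmm_em(X, K=4, seed=seed)
        lls = np.array(g.log_likelihoods)
        assert np.all(np.diff(lls) >= -1e-10)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="K=5"):
            fv.fit_gmm_em(rng.normal(size=(3, 2)), K=5, seed=0)

    def test_matches_sklearn_likelihood(self, rng):
        """Independent cross-check: our EM reaches a fit whose held-out
        log-likelihood is close to sklearn's diagonal GaussianMixture."""
        from sklearn.mixture import GaussianMixture

        X = np.vstack(
            [rng.normal((-3, 1), 1, (500, 2)), rng.normal((3, -1), 0.7, (500, 2))]
        )
        Xtest = np.vstack(
            [rng.normal((-3, 1), 1, (200, 2)), rng.normal((3, -1), 0.7, (200, 2))]
        )
        ours = fv.fit_gmm_em(X, K=2, seed=0)
        ref = GaussianMixture(2, covariance_type="diag", random_state=0).fit(X)
        assert abs(mean_log_likelihood(ours, Xtest) - ref.score(Xtest)) < 0.05


class TestPosteriors:
    def test_single_component_is_certain(self, rng):
        g = fv.GMMModel(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2)))
        P = fv.posteriors(g, rng.normal(size=(10, 2)))
        np.testing.assert_allclose(P, 1.0)

    def test_equidistant_point_splits_evenly(self):
        g = fv.GMMModel(
            np.array([0.5, 0.5]), np.array([[-1.0], [3.0]]), np.ones((2, 1))
        )
        P = fv.posteriors(g, np.array([[1.0]]))
        np.testing.assert_allclose(P, [[0.5, 0.5]], atol=1e-12)

    def test_matches_direct_density_evaluation(self):
        # hand-evaluated oracle: w_k N(x; mu_k, 1) at x=1
        g = fv.GMMModel(
            np.array([0.3, 0.7]), np.array([[0.0], [4.0]]), np.ones((2, 1))
        )
        num = np.array([0.3 * norm.pdf(1, 0, 1), 0.7 * norm.pdf(1, 4, 1)])
        expect = num / num.sum()
        P = fv.posteriors(g, np.array([[1.0]]))
        np.testing.assert_allclose(P[0], expect, atol=1e-12)

    def test_rows_sum_to_one_with_extreme_means(self):
        g = fv.GMMModel(
            np.array([0.5, 0.5]),
            np.array([[1e3, -1e3], [-1e3, 1e3]]),
            np.ones((2, 2)),
        )
        P = fv.posteriors(g, np.array([[0.0, 0.0], [500.0, -500.0]]))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestFisherVector:
    def test_single_descriptor_at_mean_closed_form(self):
        g = fv.GMMModel(np.array([1.0]), np.zeros((1, 2)), np.ones((1, 2)))
        v = fv.encode_fv(g, np.zeros((1, 2)))
        np.testing.assert_allclose(v.values, [0, 0, -1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_matches_finite_difference_oracle(self, rng):
        for _ in range(5):
            K = int(rng.integers(1, 4))
            d = int(rng.integers(1, 3))
            T = int(rng.integers(1, 11))
            g = random_gmm(rng, K, d)
            X = rng.normal(0, 2, (T, d))
            got = fv.encode_fv(g, X).values
            oracle = fv_finite_difference(g, X)
            assert np.linalg.norm(got - oracle) <= 1e-4 * max(
                np.linalg.norm(oracle), 1e-12
            )

    def test_score_is_zero_under_own_model(self, gmm2):
        X = fv.sample_from_gmm(gmm2, T=20000, seed=5).vectors
        v = fv.encode_fv(gmm2, X)
        # contributions are iid per descriptor; compare to 3 empirical SE
        se = _fv_standard_errors(gmm2, X)
        assert np.all(np.abs(v.values) <= 3 * se)

    def test_permutation_invariance_exact(self, rng, gmm2):
        X = rng.normal(size=(50, 2))
        a = fv.encode_fv(gmm2, X).values
        b = fv.encode_fv(gmm2, X[rng.permutation(50)]).values
        np.testing.assert_allclose(a, b, atol=1e-12)


def _fv_standard_errors(gmm, X):
    """Per-coordinate empirical standard errors of the FV mean."""
    gamma = fv.posteriors(gmm, X)
    sigma = np.sqrt(gmm.variances)
    z = (X[:, None, :] - gmm.means[None]) / sigma[None]
    c_mu = gamma[:, :, None] * z / np.sqrt(gmm.weights)[None, :, None]
    c_sig = gamma[:, :, None] * (z**2 - 1) / np.sqrt(2 * gmm.weights)[None, :, None]
    contrib = np.concatenate(
        [c_mu.reshape(len(X), -1), c_sig.reshape(len(X), -1)], axis=1
    )
    return contrib.std(axis=0) / np.sqrt(len(X))


class TestNormalization:
    def test_pure_l2(self):
        v = fv.EncodedVector(np.array([3.0, 4.0]), "vlad", 1, 2)
        out = fv.normalize_fv(v, alpha=1.0)
        np.testing.assert_allclose(out.values, [0.6, 0.8])

    def test_sign_preserved_under_power(self):
        v = fv.EncodedVector(np.array([-4.0, 0.0]), "vlad", 1, 2)
        out = fv.normalize_fv(v, alpha=0.5)
        np.testing.assert_allclose(out.values, [-1.0, 0.0])

    def test_unit_norm_for_nonzero_input(self, rng, gmm2):
        v = fv.encode_fv(gmm2, rng.normal(size=(30, 2)))
        assert abs(np.linalg.norm(fv.normalize_fv(v).values) - 1.0) < 1e-9

    def test_zero_stays_zero(self):
        v = fv.EncodedVector(np.zeros(4), "vlad", 2, 2)
        np.testing.assert_array_equal(fv.normalize_fv(v).values, 0.0)

    def test_invalid_alpha_rejected(self, gmm2, rng):
        v = fv.encode_fv(gmm2, rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="alpha"):
            fv.normalize_fv(v, alpha=0.0)

    def test_bovw_rejected(self, gmm2, rng):
        v = fv.encode_bovw(gmm2, rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fv or vlad"):
            fv.normalize_fv(v)


class TestBoVW:
    def test_forced_assignment_histogram(self):
        g = fv.GMMModel(
            np.full(3, 1 / 3),
            np.array([[0.0, 0], [10, 0], [0, 10]]),
            np.ones((3, 2)),
        )
        X = np.array([[0, 0], [0.1, 0], [10, 0.2], [0.3, 10]])
        v = fv.encode_bovw(g, X)
        np.testing.assert_allclose(v.values, [0.5, 0.25, 0.25])

    def test_histogram_sums_to_one(self, rng, gmm2):
        v = fv.encode_bovw(gmm2, rng.normal(size=(40, 2)))
        assert abs(v.values.sum() - 1.0) < 1e-9

    def test_all_near_first_component(self, gmm2, rng):
        X = gmm2.means[0] + 0.01 * rng.normal(size=(10, 2))
        np.testing.assert_allclose(fv.encode_bovw(gmm2, X).values, [1.0, 0.0])


class TestVLAD:
    def test_single_component_residual_sum(self, rng):
        g = fv.GMMModel(np.array([1.0]), np.array([[1.0, -1.0]]), np.ones((1, 2)))
        X = rng.normal(size=(15, 2))
        v = fv.encode_vlad(g, X)
        np.testing.assert_allclose(v.values, 15 * (X.mean(axis=0) - g.means[0]))

    def test_descriptors_at_means_give_zero(self, gmm2):
        v = fv.encode_vlad(gmm2, gmm2.means.copy())
        np.testing.assert_allclose(v.values, 0.0, atol=1e-12)

    def test_matches_brute_force_loop(self, rng, gmm2):
        X = rng.normal(0, 3, (20, 2))
        got = fv.encode_vlad(gmm2, X).values.reshape(2, 2)
        expect = np.zeros((2, 2))
        for x in X:
            k = int(np.argmax(fv.posteriors(gmm2, x[None])[0]))
            expect[k] += x - gmm2.means[k]
        np.testing.assert_allclose(got, expect, atol=1e-12)


@pytest.mark.parametrize("W", [200, 400, 600, 800, 1000])
def test_encoded_length_scales_with_vocabulary_size(W, rng):
    d = 2
    g = random_gmm(rng, W, d)
    X = rng.normal(size=(10, d))
    assert fv.encode_fv(g, X).values.size == 2 * W * d
    assert fv.encode_vlad(g, X).values.size == W * d
    assert fv.encode_bovw(g, X).values.size == W


def test_vocabulary_roundtrip(tmp_path, gmm2, rng):
    X = rng.normal(size=(50, 4))
    w = fv.fit_pca_whitener(X, 2)
    path = tmp_path / "vocab.json"
    fv.save_vocabulary(path, gmm2, w)
    g2, w2 = fv.load_vocabulary(path)
    np.testing.assert_array_equal(g2.means, gmm2.means)
    np.testing.assert_array_equal(w2.basis, w.basis)
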