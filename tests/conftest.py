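import numpy as np
import pytest
from scipy import ndimage

import fvstage as fv


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def gmm2():
    """A fixed, well-conditioned 2-component 2-D mixture."""
    return fv.GMMModel(
        weights=np.array([0.4, 0.6]),
        means=np.array([[-2.0, 0.5], [3.0, -1.0]]),
        variances=np.array([[1.0, 0.5], [2.0, 1.5]]),
    )


@pytest.fixture
def smooth_patch():
    """Smoothed random patch whose intensity orderings have clear margins."""
    p = ndimage.gaussian_filter(np.random.default_rng(2).random((21, 21)), 2.5)
    p = (p - p.min()) / (p.max() - p.min()) * 0.8 + 0.1
    return fv.GrayImage(p)


@pytest.fixture(scope="session")
def small_dataset():
    return fv.generate_dataset(n_per_stage=3, height=64, width=64, master_seed=0)


@pytest.fixture
def tiny_config():
    """A pipeline small enough for second-scale cross-validation tests."""
    return fv.PipelineConfig(
        step=16,
        patch_size=16,
        pca_dim=8,
        vocab_size=4,
        max_train_descriptors=2000,
        gmm_max_iter=30,
        folds=3,
    )


def random_gmm(rng, K, d):
    w = rng.dirichlet(np.ones(K) * 5)
    return fv.GMMModel(
        weights=w,
        means=rng.normal(0, 2, (K, d)),
        variances=rng.uniform(0.5, 2.0, (K, d)),
    )


def fv_finite_difference(gmm, X, eps=1e-5):
    """Independent Fisher-vector oracle: central finite differences of the
    mean log-likelihood w.r.t. means and standard deviations, rescaled by
    the closed-form diagonal Fisher information (sigma/sqrt(w) for means,
    sigma/sqrt(2 w) for standard deviations)."""
    from fvstage.encoding import mean_log_likelihood

    K, d = gmm.K, gmm.d
    g_mu = np.zeros((K, d))
    g_sig = np.zeros((K, d))
    sigma = np.sqrt(gmm.variances)
    for k in range(K):
        for j in range(d):
            mu_p, mu_m = gmm.means.copy(), gmm.means.copy()
            mu_p[k, j] += eps
            mu_m[k, j] -= eps
            dmu = (
                mean_log_likelihood(fv.GMMModel(gmm.weights, mu_p, gmm.variances), X)
                - mean_log_likelihood(fv.GMMModel(gmm.weights, mu_m, gmm.variances), X)
            ) / (2 * eps)
            g_mu[k, j] = dmu * sigma[k, j] / np.sqrt(gmm.weights[k])

            s_p, s_m = sigma.copy(), sigma.copy()
            s_p[k, j] += eps
            s_m[k, j] -= eps
            dsig = (
                mean_log_likelihood(fv.GMMModel(gmm.weights, gmm.means, s_p**2), X)
                - mean_log_likelihood(fv.GMMModel(gmm.weights, gmm.means, s_m**2), X)
            ) / (2 * eps)
            g_sig[k, j] = dsig * sigma[k, j] / np.sqrt(2 * gmm.weights[k])
    return np.concatenate([g_mu.ravel(), g_sig.ravel()])


def pair_count_auc(scores, positives):
    """Brute-force Mann-Whitney AUC: fraction of positive-negative pairs
    ranked correctly, ties counting one half."""
    pos = np.asarray(scores)[np.asarray(positives, dtype=bool)]
    neg = np.asarray(scores)[~np.asarray(positives, dtype=bool)]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
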