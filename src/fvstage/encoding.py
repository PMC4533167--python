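"""Image-level encoding: PCA whitening, a diagonal-covariance GMM visual
vocabulary fit by EM, and the Fisher-vector encoder with BoVW and VLAD
comparators.

The Fisher vector is the Fisher-information-normalized gradient of the
per-descriptor GMM log-likelihood with respect to the component means
and standard deviations:

    G_mu[k,j]    = 1/(T*sqrt(w_k))   * sum_t gamma_t(k) * (x_tj - mu_kj)/sigma_kj
    G_sigma[k,j] = 1/(T*sqrt(2*w_k)) * sum_t gamma_t(k) * [((x_tj - mu_kj)/sigma_kj)^2 - 1]

concatenated to a 2*K*d vector (weight-gradient terms are excluded).
PCA whitening is applied upstream so the diagonal-covariance assumption
of the GMM is reasonable for real descriptors.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "PCAWhitener",
    "GMMModel",
    "EncodedVector",
    "fit_pca_whitener",
    "fit_gmm_em",
    "posteriors",
    "encode_fv",
    "normalize_fv",
    "encode_bovw",
    "encode_vlad",
    "save_vocabulary",
    "load_vocabulary",
]

logger = logging.getLogger("fvstage")

_ENC_LENGTH = {"fv": lambda K, d: 2 * K * d, "vlad": lambda K, d: K * d,
               "bovw": lambda K, d: K}


@dataclass(frozen=True)
class PCAWhitener:
    """Linear map removing the mean and equalizing variance along the
    principal directions (unit sample covariance, ddof=1)."""

    mean: np.ndarray  # (D,)
    basis: np.ndarray  # (D, d): principal directions / singular values

    @property
    def input_dim(self) -> int:
        return self.basis.shape[0]

    @property
    def output_dim(self) -> int:
        return self.basis.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) @ self.basis


@dataclass(frozen=True)
class GMMModel:
    """Diagonal-covariance Gaussian mixture (the visual vocabulary)."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d)
    log_likelihoods: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        m = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        v = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("GMM weights must sum to 1")
        if (w <= 0).any() or (v <= 0).any():
            raise ValueError("GMM weights and variances must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "variances", v)

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class EncodedVector:
    """Fixed-length image representation (possibly concatenated over
    spatial regions)."""

    values: np.ndarray
    encoding_kind: str  # fv | vlad | bovw
    K: int
    d: int
    normalized: bool = False
    n_regions: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        expect = self.n_regions * _ENC_LENGTH[self.encoding_kind](self.K, self.d)
        if v.size != expect:
            raise ValueError(
                f"{self.encoding_kind} vector has length {v.size}, expected {expect}"
            )
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# PCA whitening


def fit_pca_whitener(X: np.ndarray, d: int) -> PCAWhitener:
    """Fit a whitening projection to the top ``d`` principal directions.

    If the data have positive variance in fewer than ``d`` directions the
    output dimension is reduced (with a warning) rather than producing a
    singular map.
    """
    X = np.asarray(X, dtype=np.float64)
    T, D = X.shape
    if d > D:
        raise ValueError(f"target dim {d} exceeds input dim {D}")
    if T <= d:
        raise ValueError("need more samples than target dimensions")
    mean = X.mean(axis=0)
    _, S, Vt = np.linalg.svd(X - mean, full_matrices=False)
    tol = S[0] * max(T, D) * np.finfo(np.float64).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank < d:
        warnings.warn(
            f"data rank {rank} < requested dim {d}; reducing output dim",
            stacklevel=2,
        )
        d = rank
    basis = Vt[:d].T / (S[:d] / np.sqrt(T - 1))
    return PCAWhitener(mean=mean, basis=basis)


# ---------------------------------------------------------------------------
# GMM via EM


def fit_gmm_em(
    X: np.ndarray,
    K: int,
    seed: int,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> GMMModel:
    """Diagonal-covariance EM from a seeded k-means++ initialization.

    The per-iteration mean log-likelihood is recorded on the model
    (``log_likelihoods``) and is non-decreasing; iteration stops when the
    relative improvement drops below ``tol``.  Variances are floored at
    1e-4 times the mean per-dimension data variance so near-duplicate
    descriptors cannot produce singular components.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    T, d = X.shape
    if T < K:
        raise ValueError(f"need at least K={K} points, got {T}")
    data_var = X.var(axis=0).mean()
    floor = max(1e-4 * data_var, 1e-12)

    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=seed)
    means = centers.astype(np.float64)
    variances = np.full((K, d), max(data_var, floor))
    weights = np.full(K, 1.0 / K)

    lls: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        log_gamma, ll = _e_step(X, weights, means, variances)
        lls.append(ll)
        gamma = np.exp(log_gamma)
        nk = gamma.sum(axis=0)
        nk = np.maximum(nk, 10 * np.finfo(np.float64).tiny)
        weights = nk / nk.sum()
        means = (gamma.T @ X) / nk[:, None]
        variances = (gamma.T @ X**2) / nk[:, None] - means**2
        variances = np.maximum(variances, floor)
        if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
            break
        prev = ll

    model = GMMModel(weights, means, variances, log_likelihoods=tuple(lls))
    logger.debug("fit_gmm_em K=%d d=%d T=%d iters=%d ll=%.6f", K, d, T, len(lls), lls[-1])
    return model


def _log_component_densities(gmm_or_params, X: np.ndarray) -> np.ndarray:
    if isinstance(gmm_or_params, GMMModel):
        w, mu, var = gmm_or_params.weights, gmm_or_params.means, gmm_or_params.variances
    else:
        w, mu, var = gmm_or_params
    X = np.atleast_2d(X)
    # (T, K): log w_k + log N(x; mu_k, diag var_k), in matmul form
    inv = 1.0 / var
    quad = X**2 @ inv.T - 2.0 * (X @ (mu * inv).T) + (mu**2 * inv).sum(axis=1)[None]
    logdet = np.log(var).sum(axis=1)
    d = X.shape[1]
    return np.log(w)[None] - 0.5 * (quad + logdet + d * np.log(2 * np.pi))


def _e_step(X, weights, means, variances):
    logp = _log_component_densities((weights, means, variances), X)
    norm = logsumexp(logp, axis=1)
    return logp - norm[:, None], float(norm.mean())


def posteriors(gmm: GMMModel, X: np.ndarray) -> np.ndarray:
    """Soft-assignment responsibilities gamma_t(k), computed in log space
    so rows sum to 1 even for components thousands of sigmas away."""
    logp = _log_component_densities(gmm, X)
    return np.exp(logp - logsumexp(logp, axis=1)[:, None])


def mean_log_likelihood(gmm: GMMModel, X: np.ndarray) -> float:
    logp = _log_component_densities(gmm, X)
    return float(logsumexp(logp, axis=1).mean())


# ---------------------------------------------------------------------------
# Encoders


def encode_fv(gmm: GMMModel, X: np.ndarray) -> EncodedVector:
    """Unnormalized Fisher vector of a descriptor set (length 2*K*d)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    T = X.shape[0]
    gamma = posteriors(gmm, X)  # (T, K)
    sigma = np.sqrt(gmm.variances)  # (K, d)
    nk = gamma.sum(axis=0)  # (K,)
    sx = gamma.T @ X  # sum_t gamma_tk x_tj
    sx2 = gamma.T @ X**2  # sum_t gamma_tk x_tj^2
    g_mu = (sx - nk[:, None] * gmm.means) / sigma
    g_mu /= T * np.sqrt(gmm.weights)[:, None]
    g_sig = (sx2 - 2.0 * gmm.means * sx + nk[:, None] * gmm.means**2) / gmm.variances
    g_sig -= nk[:, None]
    g_sig /= T * np.sqrt(2.0 * gmm.weights)[:, None]
    return EncodedVector(
        np.concatenate([g_mu.ravel(), g_sig.ravel()]), "fv", gmm.K, gmm.d
    )


def normalize_fv(v: EncodedVector, alpha: float = 0.5) -> EncodedVector:
    """Improved-FV normalization: signed power |z|^alpha then global L2."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if v.encoding_kind not in ("fv", "vlad"):
        raise ValueError("power/L2 normalization applies to fv or vlad vectors")
    z = np.sign(v.values) * np.abs(v.values) ** alpha
    n = np.linalg.norm(z)
    if n > 0:
        z = z / n
    return EncodedVector(z, v.encoding_kind, v.K, v.d, normalized=True,
                         n_regions=v.n_regions)


def _hard_assign(gmm: GMMModel, X: np.ndarray) -> np.ndarray:
    return np.argmax(posteriors(gmm, X), axis=1)  # argmax ties -> lowest k


def encode_bovw(gmm: GMMModel, X: np.ndarray) -> EncodedVector:
    """Hard-assignment visual-word histogram, L1-normalized (length K)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    counts = np.bincount(_hard_assign(gmm, X), minlength=gmm.K).astype(np.float64)
    return EncodedVector(counts / counts.sum(), "bovw", gmm.K, gmm.d, normalized=True)


def encode_vlad(gmm: GMMModel, X: np.ndarray) -> EncodedVector:
    """Per-component sums of residuals from the assigned center (K*d),
    unnormalized (apply :func:`normalize_fv`)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    assign = _hard_assign(gmm, X)
    out = np.zeros((gmm.K, gmm.d))
    np.add.at(out, assign, X - gmm.means[assign])
    return EncodedVector(out.ravel(), "vlad", gmm.K, gmm.d)


# ---------------------------------------------------------------------------
# Persistence

_FORMAT_VERSION = 1


def save_vocabulary(path, gmm: GMMModel, whitener: PCAWhitener | None = None) -> None:
    """Persist the GMM (and optional whitener) as a JSON bundle."""
    bundle = {
        "format_version": _FORMAT_VERSION,
        "gmm": {
            "weights": gmm.weights.tolist(),
            "means": gmm.means.tolist(),
            "variances": gmm.variances.tolist(),
        },
    }
    if whitener is not None:
        bundle["whitener"] = {
            "mean": whitener.mean.tolist(),
            "basis": whitener.basis.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(bundle, fh)


def load_vocabulary(path):
    with open(path) as fh:
        bundle = json.load(fh)
    if bundle.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported vocabulary format version")
    g = bundle["gmm"]
    gmm = GMMModel(np.array(g["weights"]), np.array(g["means"]),
                   np.array(g["variances"]))
    whit = None
    if "whitener" in bundle:
        w = bundle["whitener"]
        whit = PCAWhitener(np.array(w["mean"]), np.array(w["basis"]))
    return gmm, whit
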