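"""End-to-end pipeline plumbing shared by cross-validation and the CLI.

A :class:`PipelineConfig` names every knob of the staging pipeline:
pre-processing, keypoint source, descriptor kind, whitened PCA
dimension, vocabulary size, encoder and pyramid layout, and the SVM
regularization.  Feature *extraction* is deterministic per image;
everything that *learns* from data (whitener, GMM, SVM) is fit from a
training set only — see :func:`fvstage.staging.cross_validate`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import keypoints as kp_mod
from .descriptors import DescriptorSet, compute_descriptors
from .encoding import (
    GMMModel,
    PCAWhitener,
    fit_gmm_em,
    fit_pca_whitener,
)
from .image_io import GrayImage, denoise, normalize_intensity
from .spatial import PyramidLayout, encode_multilayer

__all__ = ["PipelineConfig", "extract_descriptors", "fit_vocabulary", "encode_image"]

logger = logging.getLogger("fvstage")

DETECTORS = ("dense", "dog") + kp_mod.CORNER_METHODS
DESCRIPTORS = ("sift", "daisy", "liop", "intensity", "combine")
ENCODERS = ("fv", "vlad", "bovw")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full staging pipeline."""

    detector: str = "dense"
    descriptor: str = "sift"
    denoise_method: str = "median"
    denoise_radius: int = 1
    step: int = 8
    patch_size: int = 16
    pca_dim: int = 64
    vocab_size: int = 400  # W: GMM components (W=400 is the accuracy/cost sweet spot)
    encoder: str = "fv"
    layout: tuple = ((1, 1), (2, 2))
    alpha: float = 0.5
    normalize: bool = True
    C: float = 1.0
    folds: int = 10
    max_train_descriptors: int = 100_000  # subsample cap for whitener/GMM fitting
    gmm_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.descriptor not in DESCRIPTORS:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")
        if self.encoder not in ENCODERS:
            raise ValueError(f"unknown encoder {self.encoder!r}")
        object.__setattr__(
            self, "layout", tuple((int(r), int(c)) for r, c in self.layout)
        )

    @property
    def pyramid(self) -> PyramidLayout:
        return PyramidLayout(self.layout)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "layout" in raw:
            raw["layout"] = tuple(tuple(pair) for pair in raw["layout"])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _preprocess(img: GrayImage, config: PipelineConfig) -> GrayImage:
    return normalize_intensity(
        denoise(img, method=config.denoise_method, radius=config.denoise_radius)
    )


def extract_descriptors(img: GrayImage, config: PipelineConfig) -> DescriptorSet:
    """Pre-process an image and compute its local descriptors."""
    img = _preprocess(img, config)
    if config.detector == "dense":
        kps = kp_mod.dense_grid(img, step=config.step, patch_size=config.patch_size)
    elif config.detector == "dog":
        kps = kp_mod.detect_dog(img)
    else:
        kps = kp_mod.detect_corner(img, method=config.detector)
    if not kps:
        warnings.warn("no keypoints detected; empty descriptor set", stacklevel=2)
    return compute_descriptors(img, kps, kind=config.descriptor)


def fit_vocabulary(
    descriptor_sets: list[DescriptorSet],
    config: PipelineConfig,
    seed: int,
) -> tuple[PCAWhitener, GMMModel]:
    """Fit the PCA whitener and the GMM vocabulary on pooled descriptors
    (subsampled to ``max_train_descriptors``, seeded)."""
    X = np.vstack([ds.vectors for ds in descriptor_sets if ds.T > 0])
    rng = np.random.default_rng(seed)
    if X.shape[0] > config.max_train_descriptors:
        idx = rng.choice(X.shape[0], config.max_train_descriptors, replace=False)
        X = X[idx]
    d = min(config.pca_dim, X.shape[1])
    whitener = fit_pca_whitener(X, d)
    gmm = fit_gmm_em(
        whitener.transform(X), K=config.vocab_size, seed=seed,
        max_iter=config.gmm_max_iter,
    )
    logger.info(
        "fitted vocabulary: config=%s K=%d d=%d on %d descriptors",
        config.config_hash(), gmm.K, gmm.d, X.shape[0],
    )
    return whitener, gmm


def encode_image(
    descriptors: DescriptorSet,
    whitener: PCAWhitener,
    gmm: GMMModel,
    config: PipelineConfig,
    height: int,
    width: int,
):
    """Whiten an image's descriptors and produce its multi-layer encoding."""
    white = DescriptorSet(
        whitener.transform(descriptors.vectors)
        if descriptors.T > 0
        else np.zeros((0, whitener.output_dim)),
        descriptors.coords,
        descriptors.descriptor_kind,
    )
    return encode_multilayer(
        gmm, white, height, width, layout=config.pyramid,
        encoder=config.encoder, normalize=config.normalize, alpha=config.alpha,
    )
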