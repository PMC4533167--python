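"""Supervised staging and evaluation.

Four one-vs-rest linear SVMs (class-balanced, as the stage distribution
is heavily skewed toward early stages) produce per-stage decision
scores; the predicted stage is the argmax.  Evaluation follows the
standard protocol for this task: stratified 10-fold cross-validation in
which *everything* that learns from data — PCA whitener, GMM vocabulary
and SVM — is refit inside each training fold, with per-stage and macro
sensitivity, specificity, average precision, ROC curves and AUC
(trapezoidal, equal to the Mann-Whitney pair statistic) on the pooled
test scores.  Cosine-similarity retrieval of the most similar images is
also provided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoding import EncodedVector
from .pipeline import PipelineConfig, encode_image, extract_descriptors, fit_vocabulary
from .synthetic import StagedDataset

__all__ = [
    "StagingModel",
    "EvalReport",
    "train_staging",
    "predict_scores",
    "compute_metrics",
    "stratified_folds",
    "cross_validate",
    "rank_similar",
]

logger = logging.getLogger("fvstage")

N_STAGES = 4


@dataclass(frozen=True)
class StagingModel:
    """One-vs-rest linear decision functions for the four stages."""

    coef: np.ndarray  # (4, F)
    intercept: np.ndarray  # (4,)
    C: float
    seed: int

    @property
    def n_features(self) -> int:
        return self.coef.shape[1]


@dataclass(frozen=True)
class EvalReport:
    """Cross-validated staging metrics.

    Per-stage arrays are indexed by stage 0..3; stages absent from the
    ground truth hold NaN and are excluded from the macro averages."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    average_precision: np.ndarray
    auc: np.ndarray
    macro_sensitivity: float
    macro_specificity: float
    macro_map: float
    macro_auc: float
    roc: dict  # stage -> (fpr, tpr) arrays
    confusion: np.ndarray  # (4, 4) rows = truth
    fold_assignments: np.ndarray | None = None
    pooled_scores: np.ndarray | None = None  # (N, 4) test scores, dataset order

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "average_precision": self.average_precision.tolist(),
            "auc": self.auc.tolist(),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_map": self.macro_map,
            "macro_auc": self.macro_auc,
            "roc": {
                str(s): [fpr.tolist(), tpr.tolist()] for s, (fpr, tpr) in self.roc.items()
            },
            "confusion": self.confusion.tolist(),
            "fold_assignments": (
                None
                if self.fold_assignments is None
                else self.fold_assignments.tolist()
            ),
            "pooled_scores": (
                None if self.pooled_scores is None else self.pooled_scores.tolist()
            ),
        }


def train_staging(
    features: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    seed: int = 0,
) -> StagingModel:
    """Fit four class-balanced one-vs-rest linear SVMs."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] < 8:
        raise ValueError("need at least 8 training samples")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single stage")
    coef = np.zeros((N_STAGES, X.shape[1]))
    intercept = np.full(N_STAGES, -1.0)  # stages absent from training never win
    for s in range(N_STAGES):
        pos = y == s
        if not pos.any():
            continue
        # libsvm linear SVC: hinge loss with unregularized intercept,
        # solved to tight KKT tolerance (duplication-invariant on
        # separable data, deterministic)
        clf = SVC(kernel="linear", C=C, class_weight="balanced", tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence noise on degenerate inputs
            clf.fit(X, pos.astype(int))
        coef[s] = clf.coef_[0]
        intercept[s] = clf.intercept_[0]
    return StagingModel(coef=coef, intercept=intercept, C=C, seed=seed)


def predict_scores(model: StagingModel, features: np.ndarray):
    """Per-stage decision scores (M x 4) and argmax stages (ties -> lowest)."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dim {X.shape[1]} != training dim {model.n_features}"
        )
    scores = X @ model.coef.T + model.intercept
    return scores, np.argmax(scores, axis=1)


def _trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    scores: np.ndarray,
    predicted: np.ndarray,
    truth: np.ndarray,
    fold_assignments: np.ndarray | None = None,
    keep_scores: bool = False,
) -> EvalReport:
    """One-vs-rest staging metrics.

    Sensitivity/specificity come from the hard predictions; average
    precision, ROC and AUC from the per-stage score columns.  AUC is the
    trapezoidal area under the ROC, which with the tied-score convention
    equals the Mann-Whitney pair statistic (ties count 0.5).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    sens = np.full(N_STAGES, np.nan)
    spec = np.full(N_STAGES, np.nan)
    ap = np.full(N_STAGES, np.nan)
    auc = np.full(N_STAGES, np.nan)
    roc: dict[int, tuple] = {}
    for s in range(N_STAGES):
        pos = truth == s
        if not pos.any():
            warnings.warn(f"stage {s} absent from ground truth; excluded", stacklevel=2)
            continue
        tp = int(np.sum(pos & (predicted == s)))
        fn = int(np.sum(pos & (predicted != s)))
        tn = int(np.sum(~pos & (predicted != s)))
        fp = int(np.sum(~pos & (predicted == s)))
        sens[s] = tp / (tp + fn)
        spec[s] = tn / (tn + fp) if (tn + fp) else np.nan
        if pos.all():
            ap[s] = 1.0  # no negatives: precision is 1 at every rank
        else:
            ap[s] = average_precision_score(pos, scores[:, s])
            fpr, tpr, _ = roc_curve(pos, scores[:, s])
            roc[s] = (fpr, tpr)
            auc[s] = _trapezoid_auc(fpr, tpr)
    conf = confusion_matrix(truth, predicted, labels=list(range(N_STAGES)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN macro slices
        return EvalReport(
            sensitivity=sens,
            specificity=spec,
            average_precision=ap,
            auc=auc,
            macro_sensitivity=float(np.nanmean(sens)),
            macro_specificity=float(np.nanmean(spec)),
            macro_map=float(np.nanmean(ap)),
            macro_auc=float(np.nanmean(auc)),
            roc=roc,
            confusion=conf,
            fold_assignments=fold_assignments,
            pooled_scores=scores.copy() if keep_scores else None,
        )


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment: per-stage counts across folds
    differ by at most one; every sample lands in exactly one fold."""
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(labels.size, -1)
    for fold, (_, te) in enumerate(skf.split(np.zeros(labels.size), labels)):
        folds[te] = fold
    return folds


def cross_validate(
    dataset: StagedDataset,
    config: PipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Descriptor extraction is deterministic per image and done once; the
    whitener, GMM vocabulary and SVM are refit inside each training fold
    only, so no information leaks from a fold's test images into its
    models.  Test scores are pooled over folds before computing metrics.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if config is None:
        config = PipelineConfig()
    labels = dataset.labels
    min_count = np.bincount(labels, minlength=N_STAGES)
    min_count = min_count[min_count > 0].min()
    if min_count < k:
        warnings.warn(
            f"smallest stage has {min_count} samples; reducing folds {k} -> {min_count}",
            stacklevel=2,
        )
        k = int(min_count)
    if k < 2:
        raise ValueError("need at least 2 samples per present stage")

    desc = [extract_descriptors(img, config) for img in dataset.images]
    extents = [(img.height, img.width) for img in dataset.images]

    n = len(dataset)
    folds = stratified_folds(labels, k, seed)
    scores = np.zeros((n, N_STAGES))
    for fold in range(k):
        te = np.flatnonzero(folds == fold)
        tr = np.flatnonzero(folds != fold)
        whitener, gmm = fit_vocabulary([desc[i] for i in tr], config, seed=seed + fold)
        feats = {
            i: encode_image(desc[i], whitener, gmm, config, *extents[i]).values
            for i in np.concatenate([tr, te])
        }
        model = train_staging(
            np.array([feats[i] for i in tr]), labels[tr], C=config.C, seed=seed
        )
        fold_scores, _ = predict_scores(model, np.array([feats[i] for i in te]))
        scores[te] = fold_scores
        logger.info("fold %d/%d done (train=%d test=%d)", fold + 1, k, len(tr), len(te))
    predicted = np.argmax(scores, axis=1)
    return compute_metrics(
        scores, predicted, labels, fold_assignments=folds, keep_scores=True
    )


def rank_similar(
    query: EncodedVector,
    database: list[EncodedVector],
    top_n: int = 7,
):
    """Cosine-similarity retrieval: indices of the ``top_n`` most similar
    database vectors (descending; ties -> lower index) with their scores."""
    if any(
        v.encoding_kind != query.encoding_kind or v.values.size != query.values.size
        for v in database
    ):
        raise ValueError("database vectors must match the query's kind and length")

    def unit(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    q = unit(query.values)
    sims = np.array([float(q @ unit(v.values)) for v in database])
    order = np.argsort(-sims, kind="stable")[:top_n]
    return order, sims[order]
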