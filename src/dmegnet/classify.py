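"""Marker evaluation: PCA, two-class LDA, leave-one-out CV, ROC/AUC.

The integration step's gene panels are evaluated by how well they separate
sample classes: PCA projection for visual separation, a two-class linear
discriminant classifier (diagonal-regularised pooled covariance when
features outnumber samples), leave-one-out cross-validation, and
threshold-swept ROC with trapezoidal AUC (equal to the tie-corrected
Mann-Whitney statistic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

__all__ = ["LDAModel", "ClassifierEval", "pca_project", "lda_fit", "lda_predict", "loocv", "roc_auc"]


@dataclass
class LDAModel:
    weights: np.ndarray
    threshold: float
    classes: tuple  # (class0, class1); score > threshold predicts class1
    fallback: object | None = None  # majority class when a fold is single-class

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Signed decision score per sample (rows = samples)."""
        if self.fallback is not None:
            sign = 1.0 if self.fallback == self.classes[1] else -1.0
            return np.full(np.atleast_2d(X).shape[0], sign)
        return np.atleast_2d(X) @ self.weights - self.threshold


@dataclass
class ClassifierEval:
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    auc: float = float("nan")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_true == self.y_pred))


def pca_project(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples of a feature x sample matrix onto principal components.

    Features are centred; components come from the SVD and are ordered by
    decreasing explained variance. Returns (sample x PC scores, explained
    variance ratios).
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    limit = min(X.shape)
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds min(n_features, n_samples)={limit}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), pca.explained_variance_ratio_


def lda_fit(X: np.ndarray, labels, regularize: str = "auto") -> LDAModel:
    """Fit a two-class linear discriminant (rows of X = samples).

    weights = pooled-covariance^-1 (mu1 - mu0); the decision threshold sits
    at the midpoint of the projected class means (equal priors). When
    features >= samples (or ``regularize='diagonal'``), the pooled
    covariance is reduced to its diagonal so it stays invertible.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("each class needs at least 2 samples")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    pooled = ((n0 - 1) * np.cov(X0, rowvar=False) + (n1 - 1) * np.cov(X1, rowvar=False)) / (
        n0 + n1 - 2
    )
    pooled = np.atleast_2d(pooled)
    diagonal = regularize == "diagonal" or (regularize == "auto" and X.shape[1] >= X.shape[0])
    if diagonal:
        var = np.clip(np.diag(pooled), 1e-12, None)
        w = (mu1 - mu0) / var
    else:
        w = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(w @ (mu0 + mu1) / 2.0)
    return LDAModel(weights=w, threshold=threshold, classes=(classes[0], classes[1]))


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    scores = model.decision(X)
    return np.where(scores > 0, model.classes[1], model.classes[0])


def loocv(matrix: pd.DataFrame, labels, fit=lda_fit, predict=lda_predict) -> ClassifierEval:
    """Leave-one-out cross-validation of a fit/predict pair.

    ``matrix`` is feature x sample. Each sample is predicted by a model
    fitted on the other n-1; decision scores are retained for ROC. A fold
    whose training set collapses to one class falls back to predicting the
    training majority class (logged).
    """
    X = matrix.to_numpy(dtype=float).T
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    classes = sorted(pd.unique(y).tolist())
    preds, scores = [], []
    for i in range(n):
        keep = np.arange(n) != i
        y_train = y[keep]
        try:
            model = fit(X[keep], y_train)
        except ValueError:
            majority = max(classes, key=lambda c: np.sum(y_train == c))
            logger.warning("LOOCV fold %d fell back to majority class %r", i, majority)
            model = LDAModel(
                weights=np.zeros(X.shape[1]),
                threshold=0.0,
                classes=(classes[0], classes[-1]),
                fallback=majority,
            )
        preds.append(predict(model, X[i : i + 1])[0])
        scores.append(float(model.decision(X[i : i + 1])[0]))
    return ClassifierEval(y_true=y, y_pred=np.asarray(preds), scores=np.asarray(scores))


def roc_auc(scores, labels, positive=None) -> ClassifierEval:
    """ROC curve (all thresholds, ties grouped) and trapezoidal AUC.

    AUC equals the Mann-Whitney statistic with half credit for ties,
    normalised by n_pos * n_neg.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive is None:
        positive = classes[1]
    y_bin = (y == positive).astype(int)
    fpr, tpr, _ = roc_curve(y_bin, s, drop_intermediate=False)
    auc = float(roc_auc_score(y_bin, s))
    pred = np.where(s > np.median(s), positive, [c for c in classes if c != positive][0])
    return ClassifierEval(y_true=y, y_pred=pred, scores=s, fpr=fpr, tpr=tpr, auc=auc)
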