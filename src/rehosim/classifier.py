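"""PCA-orthogonalized linear SVM for sex classification of ReHo feature maps.

Training: the n x p feature matrix (subjects x group-mask voxels) is
mean-centered, orthogonalized by PCA *without dimensionality reduction*
(all components up to the rank of the centered matrix, min(n-1, p), are
retained), and a soft-margin linear-kernel SVM is fit on the PCA scores.
Because PCA after centering is an orthonormal change of basis and the kernel
is linear, the decision function is identical (up to solver tolerance) to a
linear SVM on the centered raw features — a tested invariant.

Prediction: subtract the training mean, project onto the PCA basis, evaluate
the sign of the SVM decision function.

Labels are coded female = -1, male = +1, so back-projected voxel weights are
positive where males have higher ReHo and negative where females do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .masking import GroupMask, unvectorize

__all__ = ["TrainedClassifier", "fit", "predict", "decision_values", "accuracy", "weight_map"]

LABELS = ("female", "male")
LABEL_CODE = {"female": -1, "male": 1}
SVM_TOL = 1e-4  # fixed deterministic solver tolerance


@dataclass
class TrainedClassifier:
    """Everything needed to classify unseen subjects and back-project weights."""

    train_mean: np.ndarray          # length p
    pca_basis: np.ndarray           # p x r, orthonormal columns
    svm_weights: np.ndarray         # length r
    svm_bias: float
    cost: float = 1.0
    gmask: GroupMask | None = None

    @property
    def p(self) -> int:
        return self.train_mean.shape[0]

    @property
    def rank(self) -> int:
        return self.pca_basis.shape[1]


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "if":
        y = labels.astype(int)
        if not np.isin(y, (-1, 1)).all():
            raise ValueError("numeric labels must be -1 (female) / +1 (male)")
        return y
    y = np.array([LABEL_CODE.get(str(l)) for l in labels])
    if any(v is None for v in y.tolist()):
        bad = sorted(set(map(str, labels)) - set(LABELS))
        raise ValueError(f"unknown labels {bad}; expected {LABELS}")
    return y.astype(int)


def fit(features: np.ndarray, labels, cost: float = 1.0, gmask: GroupMask | None = None,
        scale: bool = False) -> TrainedClassifier:
    """Center, PCA-orthogonalize (full rank), and train a linear-kernel SVM.

    Parameters
    ----------
    features : ndarray, shape (n, p)
        ReHo feature matrix of the training subjects.
    labels : sequence
        "female"/"male" strings or -1/+1 codes, one per row.
    cost : float
        SVM soft-margin cost C.
    scale : bool
        Divide centered features by their per-column standard deviation
        before PCA (off by default: plain mean-centering only).
    """
    X = np.asarray(features, dtype=float)
    y = _encode(labels)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"{n} feature rows but {y.shape[0]} labels")
    if n < 4:
        raise ValueError(f"need at least 4 training subjects, got {n}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts[0] != counts[1]:
        warnings.warn(
            f"unbalanced training sample ({counts[0]} vs {counts[1]}); "
            "chance accuracy is no longer 0.5",
            stacklevel=2,
        )

    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd

    r = min(n - 1, p)
    pca = PCA(n_components=r, svd_solver="full")
    scores = pca.fit_transform(X)

    svc = SVC(kernel="linear", C=cost, tol=SVM_TOL)
    svc.fit(scores, y)

    return TrainedClassifier(
        train_mean=pca.mean_,
        pca_basis=pca.components_.T.copy(),
        svm_weights=svc.coef_[0].copy(),
        svm_bias=float(svc.intercept_[0]),
        cost=cost,
        gmask=gmask,
    )


def decision_values(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """SVM decision function on test rows: project onto PCA space, apply w.x + b."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.p:
        raise ValueError(f"feature dimension {X.shape[1]} != model p = {model.p}")
    scores = (X - model.train_mean) @ model.pca_basis
    return scores @ model.svm_weights + model.svm_bias


def predict(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Predicted sex labels ("female"/"male"); deterministic given the model."""
    d = decision_values(model, features)
    return np.where(d > 0, "male", "female")


def accuracy(predicted, truth) -> float:
    """Fraction of correctly classified subjects."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError(f"label vectors differ in shape: {predicted.shape} vs {truth.shape}")
    return float(np.mean(predicted == truth))


def weight_map(model: TrainedClassifier) -> np.ndarray:
    """Back-project SVM weights to voxel space (3D grid).

    Voxel weights are pca_basis @ svm_weights scattered to grid positions via
    the group mask; positive values mark voxels where higher ReHo pushes the
    decision toward "male".
    """
    if model.gmask is None:
        raise ValueError("model was trained without a group mask; cannot back-project")
    w_vox = model.pca_basis @ model.svm_weights
    return unvectorize(w_vox, model.gmask)
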