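"""PCA exploration and the RBF-SVM classifier with log2 grid optimization.

PCA is run on the 500-700 and 950-1300 cm^-1 ranges (where the analyte
bands live) with per-class 95% confidence ellipses on the score planes.
The SVM uses the RBF kernel exp(-g * ||x - y||^2) with one-vs-one
multi-class decomposition; the penalty C and kernel parameter g are
optimized on an integer grid of (log2 C, log2 g) in [-10, 10] with
stratified cross-validated accuracy as the objective, ties resolved toward
smaller g then smaller C (the simpler model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .features import FeatureMatrix
from .simulate import LabeledSpectrumSet

__all__ = [
    "PCA_WAVENUMBER_RANGES",
    "PCAResult",
    "SVMGridResult",
    "ClassifierReport",
    "pca_analyze",
    "svm_train",
    "svm_grid_search",
    "evaluate",
]

#: Wavenumber ranges (cm^-1) restricted to for the PCA of SERS spectra.
PCA_WAVENUMBER_RANGES = ((500.0, 700.0), (950.0, 1300.0))


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    #: per-class 95% confidence ellipse on the (PC1, PC2) plane:
    #: {label: (center(2,), axes(2,), rotation_rad)}
    ellipse_params: dict = field(default_factory=dict)


@dataclass
class SVMGridResult:
    log2C: int
    log2g: int
    objective_surface: np.ndarray
    log2C_values: np.ndarray
    log2g_values: np.ndarray
    best_objective: float

    @property
    def C(self) -> float:
        return 2.0 ** self.log2C

    @property
    def g(self) -> float:
        return 2.0 ** self.log2g


@dataclass
class ClassifierReport:
    confusion: np.ndarray
    accuracy: float
    class_labels: tuple
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "class_labels": list(self.class_labels),
            "hyperparameters": {k: _jsonable(v) for k, v in self.hyperparameters.items()},
        }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def _confidence_ellipse(points: np.ndarray, level: float = 0.95):
    """(center, semi-axes, rotation) of the chi^2 confidence ellipse of a
    2-D point cloud, from its sample covariance with 2 degrees of freedom."""
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = chi2.ppf(level, df=2)
    axes = np.sqrt(np.maximum(evals, 0.0) * scale)
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return center, axes, rotation


def pca_analyze(data: LabeledSpectrumSet | FeatureMatrix | np.ndarray,
                n_components: int = 3,
                labels: np.ndarray | None = None,
                wavenumber_ranges: tuple | None = None) -> PCAResult:
    """Mean-centred PCA with per-class 95% confidence ellipses.

    When given a :class:`LabeledSpectrumSet`, ``wavenumber_ranges`` (default
    the two characteristic-band ranges) restricts the input columns first.
    """
    if isinstance(data, LabeledSpectrumSet):
        ranges = PCA_WAVENUMBER_RANGES if wavenumber_ranges is None else wavenumber_ranges
        grid = data.wavenumbers
        mask = np.zeros(grid.size, dtype=bool)
        for lo, hi in ranges:
            mask |= (grid >= lo) & (grid <= hi)
        X = data.intensities[:, mask]
        if labels is None:
            labels = data.labels
    elif isinstance(data, FeatureMatrix):
        X = data.values
        if labels is None:
            labels = data.labels
    else:
        X = np.asarray(data, dtype=float)
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples, n_features)="
            f"{min(X.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    ellipses = {}
    if labels is not None and scores.shape[1] >= 2:
        for lab in np.unique(labels):
            pts = scores[labels == lab][:, :2]
            if pts.shape[0] >= 3:
                ellipses[int(lab)] = _confidence_ellipse(pts)
    return PCAResult(scores=scores, loadings=pca.components_.T,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     mean=pca.mean_, ellipse_params=ellipses)


def svm_train(X: np.ndarray, y: np.ndarray, C: float, g: float) -> SVC:
    """Fit a soft-margin RBF-kernel SVM (one-vs-one multi-class)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if C <= 0 or g <= 0:
        raise ValueError("C and g must both be > 0")
    if np.unique(y).size < 2:
        raise ValueError("svm_train requires at least two classes")
    model = SVC(C=C, kernel="rbf", gamma=g, decision_function_shape="ovo")
    model.fit(X, y)
    return model


def _cv_accuracy(X: np.ndarray, y: np.ndarray, C: float, g: float,
                 folds: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=False)
    scores = cross_val_score(SVC(C=C, kernel="rbf", gamma=g), X, y, cv=cv,
                             scoring="accuracy")
    return float(scores.mean())


def svm_grid_search(X: np.ndarray, y: np.ndarray,
                    log2_range: tuple[int, int] = (-10, 10),
                    objective_folds: int = 5,
                    objective=None) -> SVMGridResult:
    """Exhaustive integer-grid optimization of (log2 C, log2 g).

    ``objective(X, y, C, g) -> accuracy`` defaults to stratified
    ``objective_folds``-fold cross-validated accuracy.  Among tied maxima the
    point with the smaller log2 g, then the smaller log2 C, is returned.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if objective is None:
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("grid search requires at least two classes")
        if counts.min() < objective_folds:
            raise ValueError(
                f"smallest class has {counts.min()} samples; cannot form "
                f"{objective_folds} stratified folds"
            )
        objective = lambda X_, y_, C, g: _cv_accuracy(X_, y_, C, g, objective_folds)
    lo, hi = log2_range
    log2C_values = np.arange(lo, hi + 1)
    log2g_values = np.arange(lo, hi + 1)
    surface = np.empty((log2C_values.size, log2g_values.size))
    for i, lc in enumerate(log2C_values):
        for j, lg in enumerate(log2g_values):
            surface[i, j] = objective(X, y, 2.0 ** lc, 2.0 ** lg)
    best = surface.max()
    tied = np.argwhere(surface >= best)
    # ties -> smaller log2 g, then smaller log2 C
    j_i = min((int(j), int(i)) for i, j in tied)
    j, i = j_i
    return SVMGridResult(log2C=int(log2C_values[i]), log2g=int(log2g_values[j]),
                         objective_surface=surface,
                         log2C_values=log2C_values, log2g_values=log2g_values,
                         best_objective=float(best))


def evaluate(model, X: np.ndarray, y: np.ndarray,
             class_labels: tuple = (1, 2, 3),
             hyperparameters: dict | None = None) -> ClassifierReport:
    """Confusion matrix (rows = true, columns = predicted) and accuracy.

    ``model`` is anything with a ``predict`` method, or a callable mapping
    features to predicted labels.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    predict = model.predict if hasattr(model, "predict") else model
    yhat = np.asarray(predict(X))
    if yhat.shape[0] != y.shape[0]:
        raise ValueError("prediction length does not match label length")
    k = len(class_labels)
    index = {lab: i for i, lab in enumerate(class_labels)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y, yhat):
        confusion[index[t], index[p]] += 1
    accuracy = float(np.trace(confusion)) / len(y)
    return ClassifierReport(confusion=confusion, accuracy=accuracy,
                            class_labels=tuple(class_labels),
                            hyperparameters=hyperparameters or {})
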