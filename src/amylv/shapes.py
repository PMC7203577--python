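"""Statistical shape analysis of co-registered LV surfaces.

Aligned endo+epi surface meshes are flattened into a subjects x coordinates
matrix (3 coordinates per surface vertex; 17,376 columns for the default
template).  PCA supplies modes of variation and the low-dimensional
representation; classification of healthy vs amyloid geometries uses linear
discriminant analysis or a radial-basis kernel SVM on the PCA scores, with
leave-one-out cross-validation and sensitivity / specificity / F1 metrics.
Disease-progression shape trajectories are signed LDA distances from the
healthy group, measured with the scored patient left out of training.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .synthetic import ShapeDataset

__all__ = [
    "PCAModel",
    "ClassificationMetrics",
    "assemble_matrix",
    "fit_pca",
    "mode_shapes",
    "VarianceCappedPCA",
    "ShapeClassifier",
    "loocv_classify",
    "f1_score",
    "lda_distance",
    "shape_trajectory",
    "moods_median_test",
]

POSITIVE_CLASS = "amyloid"


def assemble_matrix(meshes, labels, subject_ids=None, scans=None) -> ShapeDataset:
    """Stack aligned meshes into the shape matrix (one row per subject-scan).

    All meshes must share the template topology; columns are ordered
    (vertex, x/y/z) with endocardial vertices first.
    """
    rows = [m.surface_coordinates() for m in meshes]
    d = {len(r) for r in rows}
    if len(d) != 1:
        raise ValueError("vertex-count mismatch: meshes are not co-registered")
    labels = np.asarray(labels)
    if len(labels) != len(rows):
        raise ValueError("need one label per mesh")
    n = len(rows)
    return ShapeDataset(
        X=np.asarray(rows),
        labels=labels,
        subject_ids=np.asarray(subject_ids if subject_ids is not None
                               else [f"s{i}" for i in range(n)]),
        scans=np.asarray(scans if scans is not None else ["baseline"] * n),
    )


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean_shape: np.ndarray
    components: np.ndarray  # (k, D), orthonormal rows
    eigenvalues: np.ndarray  # non-increasing
    n_components: int


def fit_pca(dataset: ShapeDataset, n_components: int) -> PCAModel:
    n_max = min(dataset.n_subjects - 1, dataset.X.shape[1])
    if not 1 <= n_components <= n_max:
        raise ValueError(f"n_components must lie in [1, {n_max}]")
    p = PCA(n_components=n_components).fit(dataset.X)
    return PCAModel(
        mean_shape=p.mean_,
        components=p.components_,
        eigenvalues=p.explained_variance_,
        n_components=n_components,
    )


def mode_shapes(model: PCAModel, mode: int, scale: float = 2.0):
    """Mean shape perturbed by +-scale * sqrt(eigenvalue) along one mode;
    returns (plus, minus) as (n_vertices, 3) coordinate arrays."""
    if not 0 <= mode < model.n_components:
        raise ValueError("mode index out of range")
    step = scale * np.sqrt(model.eigenvalues[mode]) * model.components[mode]
    plus = (model.mean_shape + step).reshape(-1, 3)
    minus = (model.mean_shape - step).reshape(-1, 3)
    return plus, minus


class VarianceCappedPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the smallest component count explaining >= ``variance``
    of the training variance, capped at n_samples - cap_offset (avoids
    singular within-class scatter in a downstream LDA)."""

    def __init__(self, variance: float = 0.95, cap_offset: int = 2):
        self.variance = variance
        self.cap_offset = cap_offset

    def fit(self, X, y=None):
        X = np.asarray(X)
        cap = max(1, min(len(X) - self.cap_offset, X.shape[1]))
        p = PCA(n_components=min(len(X) - 1, X.shape[1])).fit(X)
        ratio = np.cumsum(p.explained_variance_ratio_)
        k = int(np.searchsorted(ratio, self.variance) + 1)
        self.n_components_ = min(k, cap)
        self.pca_ = PCA(n_components=self.n_components_).fit(X)
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_")
        return self.pca_.transform(X)


class _MedianHeuristicSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM whose bandwidth follows the median pairwise-distance
    heuristic on the training data (gamma = 1 / (2 m^2)), unit box penalty."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X)
        from scipy.spatial.distance import pdist

        d = pdist(X)
        m = np.median(d[d > 0]) if np.any(d > 0) else 1.0
        self.gamma_ = 1.0 / (2.0 * m * m)
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma_).fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(X)


class ShapeClassifier(BaseEstimator, ClassifierMixin):
    """PCA-reduced LV shape classifier (LDA or kernel SVM).

    A scikit-learn estimator: ``fit(X, y)`` / ``predict(X)`` with PCA
    pre-processing refit on each training set, so it slots directly into
    ``LeaveOneOut`` / ``cross_val_predict`` without leakage.
    """

    def __init__(self, method: str = "lda", variance: float = 0.95, C: float = 1.0):
        self.method = method
        self.variance = variance
        self.C = C

    def _make_pipeline(self) -> Pipeline:
        if self.method == "lda":
            clf = LinearDiscriminantAnalysis()
        elif self.method == "kernel_svm":
            clf = _MedianHeuristicSVC(C=self.C)
        else:
            raise ValueError("method must be 'lda' or 'kernel_svm'")
        return Pipeline(
            [("pca", VarianceCappedPCA(variance=self.variance)), ("clf", clf)]
        )

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold lost a class; need both classes")
        self.pipeline_ = self._make_pipeline().fit(np.asarray(X), y)
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X))


# ---------------------------------------------------------------------------
# LOOCV metrics


@dataclass
class ClassificationMetrics:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def accuracy(self) -> float:
        n = self.TP + self.FP + self.FN + self.TN
        return (self.TP + self.TN) / n

    @property
    def f1(self) -> float:
        return f1_score(self.TP, self.FP, self.FN)


def f1_score(TP: int, FP: int, FN: int) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of precision and
    recall."""
    if TP < 0 or FP < 0 or FN < 0:
        raise ValueError("counts must be non-negative")
    if TP + FP + FN == 0:
        raise ValueError("F1 undefined when TP = FP = FN = 0")
    return 2.0 * TP / (2.0 * TP + FP + FN)


def loocv_classify(dataset: ShapeDataset, method: str = "lda", **clf_kwargs) -> ClassificationMetrics:
    """Leave-one-out cross-validated confusion counts (amyloid = positive).

    PCA and the classifier are refit inside every fold on the training
    subjects only.
    """
    classes = np.unique(dataset.labels)
    if len(classes) != 2:
        raise ValueError("dataset must contain exactly two classes")
    counts = np.bincount(
        np.searchsorted(classes, dataset.labels), minlength=2
    )
    if np.any(counts < 2):
        raise ValueError("need at least 2 subjects per class")

    est = ShapeClassifier(method=method, **clf_kwargs)
    tp = fp = fn = tn = 0
    for train, test in LeaveOneOut().split(dataset.X):
        y_tr = dataset.labels[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a LOOCV training fold lost a class")
        pred = clone(est).fit(dataset.X[train], y_tr).predict(dataset.X[test])[0]
        truth = dataset.labels[test][0]
        if truth == POSITIVE_CLASS:
            tp += pred == POSITIVE_CLASS
            fn += pred != POSITIVE_CLASS
        else:
            tn += pred != POSITIVE_CLASS
            fp += pred == POSITIVE_CLASS
    return ClassificationMetrics(TP=int(tp), FP=int(fp), FN=int(fn), TN=int(tn))


# ---------------------------------------------------------------------------
# LDA distance trajectories


def _lda_projector(X_tr, y_tr, variance: float):
    """Train PCA + LDA and return a normalised-distance projector."""
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training set lost a class")
    pca = VarianceCappedPCA(variance=variance).fit(X_tr)
    Z_tr = pca.transform(X_tr)
    try:
        lda = LinearDiscriminantAnalysis(n_components=1).fit(Z_tr, y_tr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class scatter after PCA; lower the variance "
            "threshold (fewer components)"
        ) from exc
    proj_tr = lda.transform(Z_tr)[:, 0]
    healthy = proj_tr[y_tr != POSITIVE_CLASS]
    sd = healthy.std(ddof=1)
    if sd == 0:
        sd = 1.0
    sign = 1.0
    amy = proj_tr[y_tr == POSITIVE_CLASS]
    if len(amy) and amy.mean() < healthy.mean():
        sign = -1.0
    mu = healthy.mean()

    def project(x_rows):
        z = pca.transform(np.atleast_2d(x_rows))
        return sign * (lda.transform(z)[:, 0] - mu) / sd

    return project


def lda_distance(dataset: ShapeDataset, subject: int, variance: float = 0.95,
                 extra_rows=None):
    """Signed LDA distance of one subject from the healthy group.

    The scored subject is excluded from training (leave-one-out); PCA
    pre-processing removes collinearity before the discriminant is fit.
    The projection is normalised by the healthy-class projection SD, so a
    distance of 0 is the healthy mean and the sign follows the healthy ->
    amyloid axis of the training cohort.  ``extra_rows`` (e.g. the same
    subject's follow-up scan) are projected with the same trained model and
    returned after the subject's own distance.
    """
    n = dataset.n_subjects
    if not 0 <= subject < n:
        raise ValueError("subject index out of range")
    mask = np.ones(n, dtype=bool)
    mask[subject] = False
    project = _lda_projector(dataset.X[mask], dataset.labels[mask], variance)
    d = float(project(dataset.X[subject])[0])
    if extra_rows is None:
        return d
    return d, [float(v) for v in project(extra_rows)]


def shape_trajectory(d_baseline: float, d_followup: float) -> str:
    """'down' (toward the healthy group) iff the distance decreased."""
    return "down" if d_followup < d_baseline else "up"


# ---------------------------------------------------------------------------


def moods_median_test(group_a, group_b) -> float:
    """Mood's median test p-value for a difference between group medians
    (2x2 contingency against the pooled median, chi-square with continuity
    correction)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0  # no information about a median difference
    res = stats.median_test(a, b, correction=True)
    p = getattr(res, "pvalue", None)
    if p is None:
        p = res[1]
    return float(p)
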