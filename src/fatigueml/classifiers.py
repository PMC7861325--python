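"""The 14-classifier zoo.

Six families: support vector machines with linear/quadratic/cubic/Gaussian
kernels (LSVM, QSVM, CSVM, GSVM), linear and quadratic discriminant
analysis (LDA, QDA), k-nearest neighbours (KNN), a CART decision tree
(TREE), Naive Bayes with box/Epanechnikov/normal/triangular event models
(NBBOX, NBEPA, NBNRM, NBTRI), and one- and two-hidden-layer multilayer
perceptrons (MLP3, MLP4 -- counting input and output layers).

scikit-learn provides everything except kernel-density Naive Bayes, which
is implemented here as a small sklearn-style estimator (per-feature 1-D
KDE per class, Silverman bandwidth).  Hyperparameters are documented
defaults, all overridable per classifier id.
"""

from __future__ import annotations

from typing import Any

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted
from sklearn.utils.multiclass import unique_labels

CLASSIFIER_IDS: tuple[str, ...] = (
    "LSVM", "QSVM", "CSVM", "GSVM",
    "LDA", "QDA",
    "KNN", "TREE",
    "NBBOX", "NBEPA", "NBNRM", "NBTRI",
    "MLP3", "MLP4",
)


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-feature kernel density estimates.

    For each class and feature, the class-conditional density is a 1-D KDE
    over the training values with the chosen kernel (``box``,
    ``triangular`` or ``epanechnikov``) and a Silverman rule-of-thumb
    bandwidth.  Class priors are the training frequencies.  A small
    density floor keeps far-from-training points from collapsing the
    posterior to exact zeros.
    """

    def __init__(self, kernel: str = "box", bandwidth: float | None = None):
        self.kernel = kernel
        self.bandwidth = bandwidth

    @staticmethod
    def _kernel_values(u: np.ndarray, kernel: str) -> np.ndarray:
        a = np.abs(u)
        if kernel == "box":
            return np.where(a <= 1.0, 0.5, 0.0)
        if kernel == "triangular":
            return np.maximum(1.0 - a, 0.0)
        if kernel == "epanechnikov":
            return np.maximum(0.75 * (1.0 - u**2), 0.0)
        raise ValueError(f"unknown kernel {kernel!r}")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        self.classes_ = unique_labels(y)
        self.train_: list[np.ndarray] = []
        self.bandwidth_: list[np.ndarray] = []
        self.log_prior_: np.ndarray = np.empty(len(self.classes_))
        for k, cls in enumerate(self.classes_):
            Xc = X[y == cls]
            self.train_.append(Xc)
            n = Xc.shape[0]
            if self.bandwidth is not None:
                h = np.full(Xc.shape[1], float(self.bandwidth))
            else:
                sd = Xc.std(axis=0, ddof=1) if n > 1 else np.ones(Xc.shape[1])
                iqr = np.subtract(*np.percentile(Xc, [75, 25], axis=0))
                spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
                h = 0.9 * spread * max(n, 2) ** (-0.2)
                h = np.where(h > 0, h, 1.0)  # degenerate feature: flat-ish
            self.bandwidth_.append(h)
            self.log_prior_[k] = np.log(n / X.shape[0])
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        floor = 1e-9
        for k in range(len(self.classes_)):
            Xc = self.train_[k]  # (n, d)
            h = self.bandwidth_[k]  # (d,)
            # u: (m, n, d)
            u = (X[:, None, :] - Xc[None, :, :]) / h
            dens = self._kernel_values(u, self.kernel).mean(axis=1) / h
            out[:, k] = self.log_prior_[k] + np.log(dens + floor).sum(axis=1)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classes_")
        jll = self._joint_log_likelihood(X)
        return self.classes_[np.argmax(jll, axis=1)]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)


class RegularizedQDA(BaseEstimator, ClassifierMixin):
    """Quadratic discriminant with ridge-regularized class covariances.

    Each class gets its own Gaussian with covariance
    ``S_c + reg * tr(S_c)/d * I`` (identity when a class is constant),
    which keeps the quadratic decision boundary well-defined even when a
    class has fewer rows than features -- the situation the all-inclusion
    feature set routinely creates in small balanced training folds.
    """

    def __init__(self, reg: float = 1e-3):
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegularizedQDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        d = X.shape[1]
        self.means_: list[np.ndarray] = []
        self.precisions_: list[np.ndarray] = []
        self.logdets_: list[float] = []
        self.log_prior_ = np.empty(len(self.classes_))
        for k, cls in enumerate(self.classes_):
            Xc = X[y == cls]
            mu = Xc.mean(axis=0)
            S = np.cov(Xc, rowvar=False, bias=False) if Xc.shape[0] > 1 else np.eye(d)
            S = np.atleast_2d(S)
            scale = np.trace(S) / d
            if scale <= 0:
                S = np.eye(d)
                scale = 1.0
            S = S + self.reg * scale * np.eye(d)
            sign, logdet = np.linalg.slogdet(S)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(S))
            self.logdets_.append(float(logdet))
            self.log_prior_[k] = np.log(Xc.shape[0] / X.shape[0])
        return self

    def _scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff = X - self.means_[k]
            maha = np.einsum("ij,jk,ik->i", diff, self.precisions_[k], diff)
            out[:, k] = self.log_prior_[k] - 0.5 * (self.logdets_[k] + maha)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._scores(X), axis=1)]


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF gamma from the median pairwise Euclidean distance:
    gamma = 1 / (2 s^2) with s the median distance (1.0 on degenerate data)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    s = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    return 1.0 / (2.0 * s * s)


def make_classifier(spec_id: str, seed: int = 0, X: np.ndarray | None = None,
                    **overrides: Any):
    """Instantiate one of the 14 classifiers by id.

    ``X`` (training features, already standardized) is only needed for
    GSVM's median-distance kernel-scale heuristic.  ``overrides`` update
    the documented default hyperparameters.
    """
    if spec_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier id {spec_id!r}")
    if spec_id == "LSVM":
        params = dict(kernel="linear", C=1.0) | overrides
        return SVC(**params)
    if spec_id == "QSVM":
        params = dict(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0) | overrides
        return SVC(**params)
    if spec_id == "CSVM":
        params = dict(kernel="poly", degree=3, coef0=1.0, gamma="scale", C=1.0) | overrides
        return SVC(**params)
    if spec_id == "GSVM":
        gamma = median_heuristic_gamma(X) if X is not None else "scale"
        params = dict(kernel="rbf", C=1.0, gamma=gamma) | overrides
        return SVC(**params)
    if spec_id == "LDA":
        return LinearDiscriminantAnalysis(**overrides)
    if spec_id == "QDA":
        params = dict(reg=1e-3) | overrides
        return RegularizedQDA(**params)
    if spec_id == "KNN":
        params = dict(n_neighbors=5, metric="euclidean") | overrides
        return KNeighborsClassifier(**params)
    if spec_id == "TREE":
        params = dict(criterion="gini", random_state=seed) | overrides
        return DecisionTreeClassifier(**params)
    if spec_id == "NBNRM":
        return GaussianNB(**overrides)
    if spec_id in {"NBBOX", "NBEPA", "NBTRI"}:
        kernel = {"NBBOX": "box", "NBEPA": "epanechnikov", "NBTRI": "triangular"}[spec_id]
        params = dict(kernel=kernel) | overrides
        return KernelNaiveBayes(**params)
    if spec_id in {"MLP3", "MLP4"}:
        hidden = (10,) if spec_id == "MLP3" else (10, 5)
        params = dict(
            hidden_layer_sizes=hidden,
            activation="logistic",
            solver="adam",
            max_iter=500,
            random_state=seed,
        ) | overrides
        return MLPClassifier(**params)
    raise AssertionError("unreachable")
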