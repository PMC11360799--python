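"""Squared Euclidean distance matrices and the majority-vote KNN classifier.

Two routes to the n x n matrix of squared pairwise distances between the
columns of a d x n matrix X:

* **naive** — Dij = sum_k (Xki - Xkj)^2 by direct expansion of the difference
  tensor; 2*d*n^2 multiply-accumulate operations (MACs), with a transient
  d x n x n intermediate.
* **gram** — the expanded form Dij = Gii + Gjj - 2*Gij with G = X^T X, the
  Gram matrix; n^2*(d+2) MACs and only n x n intermediates.  Floating-point
  cancellation can leave tiny negative entries, which are clamped to zero.

KNN ranks candidates by squared distance (order-equivalent to Euclidean
distance, no square root taken).  Distance ties break toward the lower
training index; vote ties break toward the label of the single nearest
neighbour among the tied classes, so K=2 degrades gracefully to 1-NN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "OpCounts",
    "DistanceMatrix",
    "distance_matrix_naive",
    "distance_matrix_gram",
    "cross_squared_distances",
    "knn_predict",
    "GramKNNClassifier",
]


@dataclass(frozen=True)
class OpCounts:
    """MAC and storage tallies of a distance-matrix algorithm run."""

    macs: int
    storage: int


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n matrix of squared Euclidean column distances."""

    D: np.ndarray
    op_counts: OpCounts


def _naive_counts(d: int, n: int) -> OpCounts:
    # storage: input d*n + difference tensor d*n^2 + output n^2
    return OpCounts(macs=2 * d * n * n, storage=n * n * (d + 1) + n * d)


def _gram_counts(d: int, n: int) -> OpCounts:
    # storage: input d*n + Gram matrix n^2 + output n^2
    return OpCounts(macs=n * n * (d + 2), storage=2 * n * n + d * n)


def distance_matrix_naive(X: np.ndarray) -> DistanceMatrix:
    """Squared-distance matrix by direct expansion of pairwise differences."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D d x n matrix")
    d, n = X.shape
    if n == 0:
        return DistanceMatrix(np.zeros((0, 0)), _naive_counts(d, 0))
    diff = X[:, :, None] - X[:, None, :]  # d x n x n
    D = np.einsum("kij,kij->ij", diff, diff)
    return DistanceMatrix(D, _naive_counts(d, n))


def distance_matrix_gram(X: np.ndarray) -> DistanceMatrix:
    """Squared-distance matrix via the Gram matrix G = X^T X.

    D = diag[G] + diag[G]^T - 2G, with negative cancellation residue clamped
    to zero and an exactly zero diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D d x n matrix")
    d, n = X.shape
    if n == 0:
        return DistanceMatrix(np.zeros((0, 0)), _gram_counts(d, 0))
    G = X.T @ X
    g = np.diag(G)
    D = g[:, None] + g[None, :] - 2.0 * G
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, _gram_counts(d, n))


def cross_squared_distances(
    Xtrain: np.ndarray, Xtest: np.ndarray, algorithm: str = "gram"
) -> np.ndarray:
    """Squared distances between test columns (rows of output) and train columns."""
    Xtrain = np.asarray(Xtrain, dtype=float)
    Xtest = np.asarray(Xtest, dtype=float)
    if Xtrain.shape[0] != Xtest.shape[0]:
        raise ValueError("train and test must share the feature dimension d")
    if algorithm == "naive":
        diff = Xtest[:, :, None] - Xtrain[:, None, :]
        return np.einsum("kij,kij->ij", diff, diff)
    if algorithm == "gram":
        g_tr = np.einsum("ki,ki->i", Xtrain, Xtrain)
        g_te = np.einsum("ki,ki->i", Xtest, Xtest)
        D = g_te[:, None] + g_tr[None, :] - 2.0 * (Xtest.T @ Xtrain)
        np.maximum(D, 0.0, out=D)
        return D
    raise ValueError(f"unknown algorithm {algorithm!r}; use 'naive' or 'gram'")


def _vote(neighbor_labels: np.ndarray) -> object:
    """Majority vote; ties go to the label of the nearest tied-class neighbour."""
    labels, counts = np.unique(neighbor_labels, return_counts=True)
    top = counts.max()
    tied = set(labels[counts == top])
    if len(tied) == 1:
        return tied.pop()
    for lab in neighbor_labels:  # ordered nearest-first
        if lab in tied:
            return lab
    raise AssertionError("unreachable")  # pragma: no cover


def knn_predict(
    Xtrain: np.ndarray,
    ytrain: np.ndarray,
    Xtest: np.ndarray,
    k: int = 2,
    algorithm: str = "gram",
    exclude_self: bool = False,
) -> np.ndarray:
    """Majority-vote K-nearest-neighbour prediction on d x m test columns.

    ``exclude_self`` drops, per test column j, the training column with the
    same index (for resubstitution-style evaluation on the training set).
    """
    Xtrain = np.asarray(Xtrain, dtype=float)
    ytrain = np.asarray(ytrain)
    Xtest = np.asarray(Xtest, dtype=float)
    n = Xtrain.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    n_avail = n - 1 if exclude_self else n
    if k > n_avail:
        raise ValueError(f"k={k} exceeds the {n_avail} available training columns")
    if Xtest.shape[1] == 0:
        return np.empty(0, dtype=ytrain.dtype)

    D = cross_squared_distances(Xtrain, Xtest, algorithm=algorithm)
    m = Xtest.shape[1]
    preds = np.empty(m, dtype=ytrain.dtype)
    idx = np.arange(n)
    for j in range(m):
        row = D[j]
        order = np.lexsort((idx, row))  # distance, then training index
        if exclude_self:
            order = order[order != j]
        nearest = order[:k]
        preds[j] = _vote(ytrain[nearest])
    return preds


class GramKNNClassifier(ClassifierMixin, BaseEstimator):
    """K-nearest-neighbour classifier with the Gram-trick distance backend.

    scikit-learn conventions apply: ``fit(X, y)`` with X of shape
    ``(n_samples, n_features)``; internally the columns-as-samples layout is
    used by the distance routines.

    Parameters
    ----------
    n_neighbors : int, default 2
        Number of voting neighbours K.
    algorithm : {"gram", "naive"}, default "gram"
        Distance-matrix route; both produce identical predictions.
    """

    def __init__(self, n_neighbors: int = 2, algorithm: str = "gram"):
        self.n_neighbors = n_neighbors
        self.algorithm = algorithm

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.n_neighbors > X.shape[0]:
            raise ValueError(
                f"n_neighbors={self.n_neighbors} exceeds n_samples={X.shape[0]}"
            )
        if self.algorithm not in ("gram", "naive"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.classes_ = unique_labels(y)
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return knn_predict(
            self.X_.T,
            self.y_,
            X.T,
            k=self.n_neighbors,
            algorithm=self.algorithm,
        )
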