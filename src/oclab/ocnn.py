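"""The one-class nearest-neighbor (OCNN) family: 11NN, 1KNN, J1NN, JKNN.

A test point z is scored by the ratio D_J / D_K, where D_J is the mean
distance from z to its J nearest training (target-class) neighbors and D_K
is the mean distance from each of those J neighbors to its own K nearest
training neighbors (the neighbor itself excluded). z is accepted as target
class when the score is below the threshold theta; with J = K = 1 and
theta = 1 this is the classic "is z closer to its neighbor than that
neighbor is to its own neighbor" rule.

Special cases: D_J = 0 (z coincides with a training point) scores 0 and is
accepted for any theta > 0; D_K = 0 with D_J > 0 (duplicated training
points) scores +inf and is rejected for any finite theta.

Search is exact and vectorized (full distance matrices); ties break toward
the lowest training-row index.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigError
from .preprocessing import ScalerState, fit_standardizer

#: Decision labels returned by classification.
TARGET = "target"
NON_TARGET = "non-target"

VARIANTS = ("11NN", "1KNN", "J1NN", "JKNN")


@dataclass
class NeighborQuery:
    """Result of an exact k-NN query: indices sorted by ascending distance."""

    indices: np.ndarray
    distances: np.ndarray


def knn_query(X: np.ndarray, query: np.ndarray, m: int,
              exclude_index: int | None = None) -> NeighborQuery:
    """Exact m nearest rows of X to ``query`` by Euclidean distance.

    Ties break toward the lowest row index; ``exclude_index`` removes one row
    (self-exclusion for neighbor-of-neighbor queries).
    """
    X = np.asarray(X, dtype=float)
    query = np.asarray(query, dtype=float).ravel()
    if query.shape[0] != X.shape[1]:
        raise ConfigError("query dimension does not match training data")
    d = np.linalg.norm(X - query, axis=1)
    order = np.argsort(d, kind="stable")
    if exclude_index is not None:
        order = order[order != exclude_index]
    if m > order.shape[0]:
        raise ConfigError(f"m={m} exceeds {order.shape[0]} available rows")
    sel = order[:m]
    return NeighborQuery(indices=sel, distances=d[sel])


class OCNN:
    """OCNN estimator with scikit-learn-style fit/score/classify.

    Parameters
    ----------
    J, K : int
        First- and second-stage neighbor counts.
    theta : float
        Acceptance threshold on the D_J/D_K ratio (accept iff score < theta).
    standardize : bool
        Fit a mean/sd scaler on the training target class and apply it to
        queries (recommended: Euclidean distances are scale-sensitive).
    """

    def __init__(self, J: int = 1, K: int = 1, theta: float = 1.0,
                 standardize: bool = True):
        if J < 1 or K < 1:
            raise ConfigError("J and K must be >= 1")
        if theta <= 0:
            raise ConfigError("theta must be > 0")
        self.J = J
        self.K = K
        self.theta = float(theta)
        self.standardize = standardize
        self.train_: np.ndarray | None = None
        self.scaler_: ScalerState | None = None
        self._knn_means: np.ndarray | None = None

    def fit(self, target_X: np.ndarray) -> "OCNN":
        """Store the target-class training matrix and precompute, for every
        training row, the mean distance to its own K nearest other rows."""
        X = np.asarray(target_X, dtype=float)
        if X.ndim != 2:
            raise ConfigError("training data must be 2-D")
        n = X.shape[0]
        if n < self.J + self.K:
            raise ConfigError(
                f"need at least J+K={self.J + self.K} training rows, got {n}"
            )
        if self.standardize:
            self.scaler_ = fit_standardizer(X)
            X = self.scaler_.transform(X)
        self.train_ = X
        dm = cdist(X, X)
        np.fill_diagonal(dm, np.inf)  # self-exclusion for second-stage search
        part = np.sort(dm, axis=1)[:, : self.K]
        self._knn_means = part.mean(axis=1)
        return self

    def _check_fitted(self) -> None:
        if self.train_ is None:
            raise ConfigError("estimator is not fitted")

    def score(self, Z: np.ndarray) -> np.ndarray:
        """D_J/D_K ratio for each row of Z (lower = more target-like)."""
        self._check_fitted()
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] == 0:
            return np.empty(0)
        if Z.shape[1] != self.train_.shape[1]:
            raise ConfigError("test dimension does not match training data")
        if self.scaler_ is not None:
            Z = self.scaler_.transform(Z)
        d = cdist(Z, self.train_)
        # Stable argsort keeps the lowest-index tie rule of knn_query.
        order = np.argsort(d, axis=1, kind="stable")[:, : self.J]
        rows = np.arange(Z.shape[0])[:, None]
        dj = d[rows, order].mean(axis=1)
        dk = self._knn_means[order].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(dj == 0.0, 0.0,
                              np.where(dk == 0.0, np.inf, dj / dk))
        return scores

    def classify(self, Z: np.ndarray) -> np.ndarray:
        """Label each row ``"target"`` iff its score is below theta."""
        scores = self.score(Z)
        return np.where(scores < self.theta, TARGET, NON_TARGET).astype(object)


@dataclass
class OCNNModel:
    """Plain-data view of a fitted OCNN (training matrix + parameters)."""

    train: np.ndarray
    J: int
    K: int
    theta: float
    scaler: ScalerState | None = None

    def to_estimator(self) -> OCNN:
        est = OCNN(J=self.J, K=self.K, theta=self.theta, standardize=False)
        est.fit(self.train)
        est.scaler_ = self.scaler
        return est


def ocnn_fit(target_X: np.ndarray, J: int = 1, K: int = 1, theta: float = 1.0,
             standardize: bool = False) -> OCNN:
    """Functional fit; returns a ready estimator."""
    return OCNN(J=J, K=K, theta=theta, standardize=standardize).fit(target_X)


def ocnn_score(model: OCNN, z: np.ndarray) -> float:
    """Score a single test vector with a fitted estimator."""
    return float(model.score(np.atleast_2d(z))[0])


def ocnn_classify(model: OCNN, Z: np.ndarray) -> np.ndarray:
    """Classify rows of Z; empty input yields an empty label vector."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0:
        return np.empty(0, dtype=object)
    return model.classify(Z)


def make_variant(name: str, J: int | None = None, K: int | None = None,
                 theta: float = 1.0, standardize: bool = True) -> OCNN:
    """Build an (unfitted) estimator for one of the four named variants.

    11NN forces J = K = 1; 1KNN forces J = 1; J1NN forces K = 1; JKNN is
    unconstrained. Passing a parameter that contradicts the variant's fixed
    value raises ``ConfigError``.
    """
    if name not in VARIANTS:
        raise ConfigError(f"unknown variant {name!r}; choose from {VARIANTS}")
    fixed_j = {"11NN": 1, "1KNN": 1}.get(name)
    fixed_k = {"11NN": 1, "J1NN": 1}.get(name)
    if fixed_j is not None and J not in (None, fixed_j):
        raise ConfigError(f"{name} fixes J={fixed_j}, got J={J}")
    if fixed_k is not None and K not in (None, fixed_k):
        raise ConfigError(f"{name} fixes K={fixed_k}, got K={K}")
    J = fixed_j if fixed_j is not None else (1 if J is None else J)
    K = fixed_k if fixed_k is not None else (1 if K is None else K)
    return OCNN(J=J, K=K, theta=theta, standardize=standardize)
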