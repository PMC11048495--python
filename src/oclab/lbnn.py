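"""Location-based Nearest Neighbor (LBNN) one-class classification.

LBNN first clusters the target-class training data with KMOR (dropping the
outlier cluster), then classifies a test point t cluster by cluster: the
nearest member of cluster c is t's *reference point*; if t's distance to the
reference is below the Q-th percentile of the reference point's distances to
the other members of its cluster, t is accepted as target class (scanning
clusters in index order with an early break). The percentile threshold
adapts to local density: a reference deep inside a tight cluster has a small
threshold, one at a sparse fringe a large one.

The hard decision is complemented by a continuous score, min over clusters
of d / threshold: score < 1 is exactly equivalent to acceptance, and the
score serves as the ROC/AUC statistic (higher = more outlying).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigError, DegenerateInputError
from .kmor import OUTLIER_LABEL, KMORConfig, KMORResult, kmor_fit, kmor_select_k
from .preprocessing import ScalerState, fit_standardizer


def percentile(values: np.ndarray, Q: float) -> float:
    """Linear-interpolation percentile: rank r = Q*(m-1) between order stats.

    Q = 0 gives the minimum, Q = 1 the maximum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("percentile of an empty vector is undefined")
    if not 0.0 <= Q <= 1.0:
        raise ConfigError("Q must lie in [0, 1]")
    return float(np.quantile(values, Q))


@dataclass
class LBNNDecision:
    """Per-point decision detail for inspection and testing."""

    accepted: int
    reference_indices: list[int]
    reference_distances: list[float]
    thresholds: list[float]
    deciding_cluster: int | None
    n_distance_evals: int


@dataclass
class LBNNModel:
    """Fitted LBNN state: per-cluster member matrices plus percentile Q."""

    clusters: list[np.ndarray]
    Q: float
    kmor_result: KMORResult
    scaler: ScalerState | None = None
    # Q-percentile of each member's distances to the other members, per cluster
    member_thresholds: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_thresholds:
            for members in self.clusters:
                dm = cdist(members, members)
                m = members.shape[0]
                thr = np.empty(m)
                for r in range(m):
                    others = np.delete(dm[r], r)
                    thr[r] = percentile(others, self.Q)
                self.member_thresholds.append(thr)


def _merge_singletons(assignments: np.ndarray, centers: np.ndarray,
                      X: np.ndarray) -> np.ndarray:
    """Reassign members of 1-row clusters to the nearest other cluster.

    A singleton cluster has no within-cluster distances, so its percentile
    threshold would be undefined; merging preserves every training point
    while keeping thresholds well-defined.
    """
    assignments = assignments.copy()
    while True:
        labels, counts = np.unique(assignments[assignments != OUTLIER_LABEL],
                                   return_counts=True)
        if len(labels) <= 1:
            break
        singles = labels[counts == 1]
        if len(singles) == 0:
            break
        c = int(singles[0])
        idx = int(np.flatnonzero(assignments == c)[0])
        other = [int(l) for l in labels if l != c]
        d = [np.linalg.norm(X[idx] - centers[o]) for o in other]
        assignments[idx] = other[int(np.argmin(d))]
    return assignments


def lbnn_fit(target_X: np.ndarray, kmor_config: KMORConfig | None = None,
             Q: float = 0.9, k_candidates=None,
             standardize: bool = False) -> LBNNModel:
    """Cluster the target class with KMOR and freeze per-member thresholds.

    ``k_candidates`` triggers objective-based cluster-count selection (each
    candidate fitted with restarts); otherwise the fixed ``kmor_config.k`` is
    used. KMOR outlier-cluster members are dropped: they are by construction
    non-representative and never serve as reference points.
    """
    if not 0.0 <= Q <= 1.0:
        raise ConfigError("Q must lie in [0, 1]")
    X = np.asarray(target_X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigError("LBNN needs at least 2 training rows")
    scaler = None
    if standardize:
        scaler = fit_standardizer(X)
        X = scaler.transform(X)
    config = kmor_config or KMORConfig()
    if k_candidates is not None:
        _, results = kmor_select_k(X, k_candidates, config)
        result = results[min(results, key=lambda k: (results[k].objective, k))]
    else:
        result = kmor_fit(X, config)

    assignments = _merge_singletons(result.assignments, result.centers, X)
    clusters = []
    for j in range(config.k if k_candidates is None else result.centers.shape[0]):
        members = X[assignments == j]
        if members.shape[0] >= 2:
            clusters.append(members)
    if not clusters:
        raise DegenerateInputError(
            "KMOR left no cluster with >= 2 members; cannot fit LBNN"
        )
    return LBNNModel(clusters=clusters, Q=Q, kmor_result=result, scaler=scaler)


def lbnn_decide(model: LBNNModel, t: np.ndarray) -> LBNNDecision:
    """Full decision detail for one test vector (Algorithm-style scan)."""
    t = np.asarray(t, dtype=float).ravel()
    if model.scaler is not None:
        t = model.scaler.transform(t[None, :])[0]
    refs, dists, thrs = [], [], []
    deciding = None
    n_evals = 0
    for c, members in enumerate(model.clusters):
        d = np.linalg.norm(members - t, axis=1)
        n_evals += members.shape[0]
        r = int(np.argmin(d))  # first minimum = lowest index tie rule
        d_ref = float(d[r])
        thr = float(model.member_thresholds[c][r])
        n_evals += members.shape[0] - 1  # the |L| distances behind the threshold
        refs.append(r)
        dists.append(d_ref)
        thrs.append(thr)
        if d_ref < thr:
            deciding = c
            break
    return LBNNDecision(
        accepted=1 if deciding is not None else 0,
        reference_indices=refs,
        reference_distances=dists,
        thresholds=thrs,
        deciding_cluster=deciding,
        n_distance_evals=n_evals,
    )


def lbnn_classify(model: LBNNModel, T: np.ndarray) -> np.ndarray:
    """Hard decisions (1 = accepted as target class) for rows of T."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    return np.array([lbnn_decide(model, t).accepted for t in T], dtype=int)


def lbnn_score(model: LBNNModel, t: np.ndarray) -> float:
    """Continuous outlyingness: min over clusters of d / threshold.

    score < 1 iff :func:`lbnn_classify` accepts. A zero threshold with any
    positive (or zero) distance yields +inf (that cluster can accept
    nothing under the strict < rule).
    """
    t = np.asarray(t, dtype=float).ravel()
    if model.scaler is not None:
        t = model.scaler.transform(t[None, :])[0]
    best = np.inf
    for c, members in enumerate(model.clusters):
        d = np.linalg.norm(members - t, axis=1)
        r = int(np.argmin(d))
        thr = float(model.member_thresholds[c][r])
        ratio = float(d[r]) / thr if thr > 0 else np.inf
        best = min(best, ratio)
    return best


def lbnn_scores(model: LBNNModel, T: np.ndarray) -> np.ndarray:
    """Vector of continuous scores for rows of T."""
    T = np.atleast_2d(np.asarray(T, dtype=float))
    return np.array([lbnn_score(model, t) for t in T], dtype=float)


class LBNN:
    """Estimator facade: fit/classify/score with internal standardization."""

    def __init__(self, kmor_config: KMORConfig | None = None, Q: float = 0.9,
                 k_candidates=None, standardize: bool = True):
        self.kmor_config = kmor_config
        self.Q = Q
        self.k_candidates = k_candidates
        self.standardize = standardize
        self.model_: LBNNModel | None = None

    def fit(self, target_X: np.ndarray) -> "LBNN":
        self.model_ = lbnn_fit(target_X, self.kmor_config, self.Q,
                               self.k_candidates, standardize=self.standardize)
        return self

    def _check(self) -> LBNNModel:
        if self.model_ is None:
            raise ConfigError("estimator is not fitted")
        return self.model_

    def classify(self, T: np.ndarray) -> np.ndarray:
        return lbnn_classify(self._check(), T)

    def score(self, T: np.ndarray) -> np.ndarray:
        return lbnn_scores(self._check(), T)
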