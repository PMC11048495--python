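"""K-means with outlier removal (KMOR).

KMOR extends Lloyd's K-means with an extra cluster (index k+1 in the usual
1-based notation; label ``-1`` here) that absorbs outliers. The objective is

    P(U, Z) = sum_{inliers} ||x_i - z_{c(i)}||^2  +  n_out * D(U, Z)

where D(U, Z) = gamma * (inlier SSE) / (n - n_out) is gamma times the mean
squared distance of current non-outliers to their centers. A point becomes an
outlier when its squared distance to the nearest center exceeds D(U, Z); the
total number of outliers is capped at n0. With n0 = 0 the algorithm reduces
exactly to Lloyd's K-means.

Assignment labels: clusters are 0..k-1, outliers are ``OUTLIER_LABEL = -1``.
All distances inside the objective are squared Euclidean; the reported
threshold ``d_threshold_final`` is in squared units.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ConfigError, DegenerateInputError

#: Assignment label of the outlier (k+1) cluster.
OUTLIER_LABEL = -1


@dataclass(frozen=True)
class KMORConfig:
    """KMOR parameters.

    ``gamma`` is the weight of the average distance in the outlier threshold
    (reported as lambda = 2.5 in the reference experiment configuration);
    ``n0_fraction`` caps outliers at floor(n0_fraction * n); ``delta`` is the
    absolute convergence tolerance on the objective.
    """

    k: int = 1
    gamma: float = 2.5
    n0_fraction: float = 0.05
    delta: float = 1e-6
    itermax: int = 100
    seed: int = 0
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.gamma <= 0:
            raise ConfigError("gamma must be > 0")
        if not 0.0 <= self.n0_fraction < 1.0:
            raise ConfigError(
                "n0_fraction must lie in [0, 1): at least one inlier is required"
            )
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if self.itermax < 1:
            raise ConfigError("itermax must be >= 1")
        if self.n_restarts < 1:
            raise ConfigError("n_restarts must be >= 1")


@dataclass
class KMORResult:
    """Outcome of one KMOR run.

    ``objective_trace`` starts with the objective of the initial no-outlier
    assignment and then holds P(U, Z) after every Rule-1/Rule-2 sweep; it is
    non-increasing. ``cap_hit`` records whether the n0 cap ever trimmed the
    Rule-1 outlier set in the final iteration (in which case some points may
    sit beyond ``d_threshold_final`` while assigned to a regular cluster).
    """

    assignments: np.ndarray
    centers: np.ndarray
    objective_trace: np.ndarray
    n_iterations: int
    d_threshold_final: float
    cap_hit: bool
    config: KMORConfig
    outlier_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.outlier_indices = np.flatnonzero(self.assignments == OUTLIER_LABEL)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def kmor_objective(X: np.ndarray, assignments: np.ndarray,
                   centers: np.ndarray, gamma: float) -> float:
    """Evaluate P(U, Z) for a given assignment and center set.

    Raises
    ------
    DegenerateInputError
        If every point is an outlier (the average-distance term has a zero
        denominator).
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    inlier = assignments != OUTLIER_LABEL
    n = X.shape[0]
    n_out = int(n - inlier.sum())
    if n_out == n:
        raise DegenerateInputError("objective undefined: all points are outliers")
    diffs = X[inlier] - centers[assignments[inlier]]
    sse = float(np.einsum("ij,ij->", diffs, diffs))
    d_threshold = gamma * sse / (n - n_out)
    return sse + n_out * d_threshold


def _nearest(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index of the nearest center and squared distance to it, per point."""
    d2 = cdist(X, centers, metric="sqeuclidean")
    idx = np.argmin(d2, axis=1)
    return idx, d2[np.arange(X.shape[0]), idx]


def kmor_fit(X: np.ndarray, config: KMORConfig, callback=None) -> KMORResult:
    """Run KMOR, keeping the best of ``config.n_restarts`` seeded starts.

    Random initialization (k distinct rows as centers) makes a single run
    vulnerable to local minima — e.g. a far outlier drawn as an initial
    center anchors its own cluster and is never removed — so the fit repeats
    the sweep from ``n_restarts`` independent seeded initializations and
    returns the run with the lowest final objective. Set ``n_restarts=1``
    for the bare single-start sweep.

    ``callback(iteration, assignments, centers)`` is invoked after every
    sweep (iteration 0 = initial assignment) for instrumentation; it
    requires ``n_restarts=1`` so the reported sequence is unambiguous.
    """
    if callback is not None and config.n_restarts != 1:
        raise ConfigError("callback instrumentation requires n_restarts=1")
    if config.n_restarts == 1:
        return _kmor_single(X, config, config.seed, callback)
    seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=config.n_restarts
    )
    best: KMORResult | None = None
    for s in seeds:
        res = _kmor_single(X, config, int(s))
        if best is None or res.objective < best.objective:
            best = res
    return best


def _kmor_single(X: np.ndarray, config: KMORConfig, init_seed: int,
                 callback=None) -> KMORResult:
    """One Rule-1/Rule-2 sweep sequence from a single seeded initialization.

    Initialization picks ``k`` distinct rows of ``X`` as centers and assigns
    every point to its nearest center (no outliers yet). Each sweep then
    applies Rule 1 (re-assign, sending points with nearest-center squared
    distance above the current threshold D(U, Z) to the outlier cluster,
    greedily capped at n0 by keeping the largest distances) and Rule 2
    (centers = mean of member points, outliers excluded), until the objective
    changes by less than ``delta`` or ``itermax`` sweeps are done.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigError("X must be 2-D")
    n, _ = X.shape
    k = config.k
    if k > n:
        raise ConfigError(f"k={k} exceeds n={n}")
    n0 = math.floor(config.n0_fraction * n)

    rng = np.random.default_rng(init_seed)
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    assignments, _ = _nearest(X, centers)
    trace = [kmor_objective(X, assignments, centers, config.gamma)]
    if callback is not None:
        callback(0, assignments.copy(), centers.copy())

    d_threshold = math.nan
    cap_hit = False
    iteration = 0
    while True:
        # Rule 1: threshold from the *current* assignment and centers.
        inlier = assignments != OUTLIER_LABEL
        diffs = X[inlier] - centers[assignments[inlier]]
        sse = float(np.einsum("ij,ij->", diffs, diffs))
        d_threshold = config.gamma * sse / int(inlier.sum())

        nearest_idx, nearest_d2 = _nearest(X, centers)
        out_mask = nearest_d2 > d_threshold
        cap_hit = False
        if out_mask.sum() > n0:
            cap_hit = True
            candidates = np.flatnonzero(out_mask)
            order = np.argsort(-nearest_d2[candidates], kind="stable")
            keep = candidates[order[:n0]]
            out_mask = np.zeros(n, dtype=bool)
            out_mask[keep] = True
        assignments = np.where(out_mask, OUTLIER_LABEL, nearest_idx)

        # Rule 2: update centers from member points; repair empty clusters
        # by re-seeding with the farthest current non-outlier point.
        inlier = ~out_mask
        for j in range(k):
            members = X[assignments == j]
            if members.shape[0] > 0:
                centers[j] = members.mean(axis=0)
        for j in range(k):
            if not np.any(assignments == j):
                _, d2 = _nearest(X, centers)
                d2[~inlier] = -np.inf
                far = int(np.argmax(d2))
                centers[j] = X[far]
                assignments[far] = j

        iteration += 1
        trace.append(kmor_objective(X, assignments, centers, config.gamma))
        if callback is not None:
            callback(iteration, assignments.copy(), centers.copy())
        if abs(trace[-1] - trace[-2]) < config.delta or iteration >= config.itermax:
            break

    return KMORResult(
        assignments=assignments,
        centers=centers,
        objective_trace=np.asarray(trace),
        n_iterations=iteration,
        d_threshold_final=d_threshold,
        cap_hit=cap_hit,
        config=config,
    )


def kmor_select_k(X: np.ndarray, k_candidates, config: KMORConfig
                  ) -> tuple[int, dict[int, KMORResult]]:
    """Fit each candidate k with ``n_restarts`` seeded initializations.

    Keeps the best-objective run per k and returns the k whose final
    objective is minimal (ties toward the smallest k). Note the objective
    typically decreases with k, so candidates must be a deliberate, bounded
    list; the full objective-vs-k curve is available through the returned
    per-k results.
    """
    k_candidates = list(k_candidates)
    if not k_candidates:
        raise ConfigError("k_candidates must be non-empty")
    seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=len(k_candidates)
    )
    results: dict[int, KMORResult] = {}
    for i, k in enumerate(k_candidates):
        cfg = KMORConfig(
            k=k, gamma=config.gamma, n0_fraction=config.n0_fraction,
            delta=config.delta, itermax=config.itermax,
            seed=int(seeds[i]), n_restarts=config.n_restarts,
        )
        results[k] = kmor_fit(X, cfg)
    k_best = min(results, key=lambda k: (results[k].objective, k))
    return k_best, results


def kmor_outliers(X: np.ndarray, config: KMORConfig) -> np.ndarray:
    """Indices flagged as outliers by a single KMOR run."""
    return kmor_fit(X, config).outlier_indices
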