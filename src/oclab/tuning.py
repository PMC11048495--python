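"""Parameter optimization from one-class data via proxy outliers.

One-class training data contain no negatives to tune against, so the
toolkit manufactures some: outliers detected inside the target class (by an
IQR fence on nearest-neighbor distances, or by KMOR) are relabeled as
stand-in non-target samples. The resulting tiny binary "proxy dataset"
drives a stratified inner-CV grid search over (J, K) for JKNN and a scan of
data-driven theta candidates (per-point D1/D11 ratios) for the thresholded
variants, both scored by G-means.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .datasets import NEGATIVE, POSITIVE
from .exceptions import ConfigError, DegenerateInputError
from .kmor import KMORConfig, kmor_outliers, kmor_select_k
from .metrics import compute_metrics, confusion
from .ocnn import NON_TARGET, TARGET, OCNN

logger = logging.getLogger(__name__)

#: Proxy label of detected outliers (they play the non-target role).
PROXY_OUTLIER = "proxy-outlier"


@dataclass
class ProxyDataset:
    """Target-class training data with outlier-derived proxy labels."""

    features: np.ndarray
    proxy_labels: np.ndarray  # values in {TARGET, PROXY_OUTLIER}
    source: str               # "iqr" or "kmor"

    @property
    def n_proxy_outliers(self) -> int:
        return int(np.sum(self.proxy_labels == PROXY_OUTLIER))


@dataclass
class JKGrid:
    """Mean inner-CV G-means for every (J, K) cell; NaN marks infeasible cells."""

    J_values: list[int]
    K_values: list[int]
    score_matrix: np.ndarray


@dataclass
class ThetaScan:
    """Pooled D1/D11 threshold candidates with their CV G-means."""

    candidates: np.ndarray
    gmeans_by_candidate: np.ndarray
    theta_best: float
    fallback_used: bool = False


def iqr_outliers(X: np.ndarray) -> np.ndarray:
    """Points whose 1-NN distance exceeds the Tukey fence Q3 + 1.5 IQR.

    Distances are each point's Euclidean distance to its nearest *other*
    point; quartiles use linear interpolation. Known blind spot: a tight
    pair of far-away outliers gives both members a 1-NN distance of ~0, so
    neither is flagged.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise DegenerateInputError("IQR detection needs at least 4 points")
    dm = cdist(X, X)
    np.fill_diagonal(dm, np.inf)
    nn = dm.min(axis=1)
    q1, q3 = np.percentile(nn, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return np.flatnonzero(nn > fence)


def build_proxy_dataset(target_X: np.ndarray, method: str = "iqr",
                        kmor_config: KMORConfig | None = None,
                        k_candidates=None) -> ProxyDataset:
    """Label detected outliers as proxy non-targets, the rest as target.

    ``method`` selects the detector: "iqr" (nearest-neighbor distance fence)
    or "kmor" (the outlier cluster of a KMOR fit; when ``k_candidates`` is
    given, the cluster count is first selected by minimum objective). A
    detection that finds nothing yields an all-target proxy dataset and a
    warning; downstream optimizers then fall back to defaults.
    """
    X = np.asarray(target_X, dtype=float)
    if X.shape[0] == 0:
        raise ConfigError("target_X must be non-empty")
    if method == "iqr":
        out_idx = iqr_outliers(X)
    elif method == "kmor":
        cfg = kmor_config or KMORConfig()
        if k_candidates is not None:
            k_best, results = kmor_select_k(X, k_candidates, cfg)
            out_idx = results[k_best].outlier_indices
        else:
            out_idx = kmor_outliers(X, cfg)
    else:
        raise ConfigError(f"unknown detection method {method!r}")
    labels = np.full(X.shape[0], TARGET, dtype=object)
    labels[out_idx] = PROXY_OUTLIER
    if len(out_idx) == 0:
        warnings.warn(
            f"{method} detected no outliers in the target class; "
            "parameter optimization will fall back to defaults"
        )
    return ProxyDataset(features=X, proxy_labels=labels, source=method)


def _proxy_folds(proxy: ProxyDataset, inner_folds: int, seed: int):
    """Stratified folds over {target, proxy-outlier}; stratification matters
    because proxy-outlier counts are tiny."""
    if inner_folds < 2:
        raise ConfigError("inner_folds must be >= 2")
    y = (proxy.proxy_labels == PROXY_OUTLIER).astype(int)
    n_out = int(y.sum())
    n_splits = min(inner_folds, n_out, len(y) - n_out)
    if n_splits < 2:
        # Too few of one class to stratify: plain seeded shuffle split.
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(y))
        half = len(y) // 2
        return [(order[half:], order[:half]), (order[:half], order[half:])]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    return list(skf.split(proxy.features, y))


def _fold_gmeans(y_true_is_proxy: np.ndarray, pred_labels: np.ndarray) -> float | None:
    """G-means of one validation fold, proxy-outlier playing positive."""
    y_true = np.where(y_true_is_proxy, POSITIVE, NEGATIVE).astype(object)
    y_pred = np.where(pred_labels == NON_TARGET, POSITIVE, NEGATIVE).astype(object)
    report = compute_metrics(confusion(y_true, y_pred))
    return report.gmeans


def optimize_jk(proxy: ProxyDataset, J_values=None, K_values=None,
                inner_folds: int = 2, seed: int = 0
                ) -> tuple[int, int, JKGrid]:
    """Grid-search (J, K) for JKNN (theta = 1) on the proxy dataset.

    Each fold fits JKNN on the fold's target-labeled rows only and evaluates
    on the held-out mix; a cell's score is the mean fold G-means. Cells where
    J + K exceeds the smallest target-only training part are NaN and excluded
    from the argmax. Ties break toward the smallest J, then smallest K.
    """
    J_values = list(J_values) if J_values is not None else list(range(1, 11))
    K_values = list(K_values) if K_values is not None else list(range(1, 11))
    grid = JKGrid(J_values, K_values,
                  np.full((len(J_values), len(K_values)), np.nan))
    if proxy.n_proxy_outliers == 0:
        warnings.warn("no proxy outliers: returning default J=1, K=1")
        return 1, 1, grid

    folds = _proxy_folds(proxy, inner_folds, seed)
    is_proxy = proxy.proxy_labels == PROXY_OUTLIER
    fold_data = []
    for tr, va in folds:
        tr_target = tr[~is_proxy[tr]]
        fold_data.append((proxy.features[tr_target], va))
    min_train = min(ft.shape[0] for ft, _ in fold_data)

    for a, J in enumerate(J_values):
        for b, K in enumerate(K_values):
            if J + K > min_train:
                continue  # infeasible cell: left NaN
            scores = []
            for X_tr, va in fold_data:
                model = OCNN(J=J, K=K, theta=1.0, standardize=False).fit(X_tr)
                gm = _fold_gmeans(is_proxy[va], model.classify(proxy.features[va]))
                if gm is not None:
                    scores.append(gm)
            if scores:
                grid.score_matrix[a, b] = float(np.mean(scores))

    best = None
    for a, J in enumerate(J_values):
        for b, K in enumerate(K_values):
            s = grid.score_matrix[a, b]
            if np.isnan(s):
                continue
            if best is None or s > best[0]:
                best = (s, J, K)
    if best is None:
        warnings.warn("no feasible (J, K) cell: returning default J=1, K=1")
        return 1, 1, grid
    return best[1], best[2], grid


def optimize_theta(proxy: ProxyDataset, inner_folds: int = 2, seed: int = 0,
                   theta_fallback: float = 1.5) -> ThetaScan:
    """Scan data-driven theta candidates for the 11NN(theta) rule.

    For every validation point across the inner folds, the candidate is its
    D1/D11 ratio against the fold's target-only training part (1-NN distance
    divided by that neighbor's own 1-NN distance). Because the 11NN score of
    a validation point *is* that same ratio, each candidate theta is then
    evaluated by thresholding the pooled per-fold scores (accept iff
    score < theta) and averaging fold G-means. Ties break toward the
    smallest theta. Candidates with D11 = 0 are skipped and logged; if no
    candidate is usable the configured fallback theta is returned.
    """
    if proxy.n_proxy_outliers == 0:
        warnings.warn(f"no proxy outliers: returning fallback theta={theta_fallback}")
        return ThetaScan(np.empty(0), np.empty(0), theta_fallback, fallback_used=True)

    folds = _proxy_folds(proxy, inner_folds, seed)
    is_proxy = proxy.proxy_labels == PROXY_OUTLIER
    per_fold = []  # (scores of validation points, is_proxy flags)
    candidates = []
    for tr, va in folds:
        tr_target = tr[~is_proxy[tr]]
        X_tr = proxy.features[tr_target]
        if X_tr.shape[0] < 2:
            continue
        model = OCNN(J=1, K=1, theta=1.0, standardize=False).fit(X_tr)
        scores = model.score(proxy.features[va])
        per_fold.append((scores, is_proxy[va]))
        for s in scores:
            if np.isfinite(s) and s > 0:
                candidates.append(float(s))
            else:
                logger.info("skipping degenerate theta candidate (D11=0 or D1=0)")
    if not candidates:
        warnings.warn(f"no usable theta candidates: falling back to {theta_fallback}")
        return ThetaScan(np.empty(0), np.empty(0), theta_fallback, fallback_used=True)

    candidates = np.asarray(sorted(candidates))
    gm_by_cand = np.empty(len(candidates))
    for i, theta in enumerate(candidates):
        fold_scores = []
        for scores, val_proxy in per_fold:
            pred = np.where(scores < theta, TARGET, NON_TARGET).astype(object)
            gm = _fold_gmeans(val_proxy, pred)
            if gm is not None:
                fold_scores.append(gm)
        gm_by_cand[i] = np.mean(fold_scores) if fold_scores else np.nan
    usable = ~np.isnan(gm_by_cand)
    best_idx = int(np.flatnonzero(usable)[np.argmax(gm_by_cand[usable])])
    # candidates are sorted ascending and argmax returns the first maximum,
    # so ties already resolve toward the smallest theta
    return ThetaScan(candidates=candidates, gmeans_by_candidate=gm_by_cand,
                     theta_best=float(candidates[best_idx]))


def optimize_q(proxy: ProxyDataset, kmor_config: KMORConfig | None = None,
               Q_grid=None, k_candidates=None, inner_folds: int = 2,
               seed: int = 0) -> tuple[float, dict[float, float]]:
    """Scan percentile levels Q for the location-based classifier.

    Mirrors the proxy-outlier philosophy of the other optimizers: each Q on
    the grid is scored by stratified inner-CV G-means of a location-based
    model fitted on the fold's target-labeled rows; ties break toward the
    smallest Q. Returns the chosen Q and the per-Q mean scores (NaN where no
    fold was scorable). Falls back to Q = 0.9 when there are no proxies.
    """
    from .lbnn import lbnn_classify, lbnn_fit  # local import: cycle guard

    Q_grid = sorted(Q_grid) if Q_grid is not None else [0.5, 0.75, 0.9, 0.95, 1.0]
    if proxy.n_proxy_outliers == 0:
        warnings.warn("no proxy outliers: returning default Q=0.9")
        return 0.9, {float(q): np.nan for q in Q_grid}

    folds = _proxy_folds(proxy, inner_folds, seed)
    is_proxy = proxy.proxy_labels == PROXY_OUTLIER
    scores: dict[float, float] = {}
    for Q in Q_grid:
        fold_scores = []
        for tr, va in folds:
            X_tr = proxy.features[tr[~is_proxy[tr]]]
            if X_tr.shape[0] < 2:
                continue
            model = lbnn_fit(X_tr, kmor_config or KMORConfig(), Q=float(Q),
                             k_candidates=k_candidates)
            accepted = lbnn_classify(model, proxy.features[va])
            pred = np.where(accepted == 1, TARGET, NON_TARGET).astype(object)
            gm = _fold_gmeans(is_proxy[va], pred)
            if gm is not None:
                fold_scores.append(gm)
        scores[float(Q)] = float(np.mean(fold_scores)) if fold_scores else np.nan
    usable = {q: s for q, s in scores.items() if not np.isnan(s)}
    if not usable:
        warnings.warn("no scorable Q on the grid: returning default Q=0.9")
        return 0.9, scores
    q_best = min(usable, key=lambda q: (-usable[q], q))
    return q_best, scores
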