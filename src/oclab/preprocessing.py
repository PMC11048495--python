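"""Feature standardization and stepwise forward feature selection.

Distance-based one-class methods are scale-sensitive, so every estimator in
this toolkit standardizes by default using statistics fit on the training
target class only. The stepwise selector implements greedy forward selection
scored by cross-validated AUC: each round, every remaining feature is tried
jointly with the already-kept set, and the feature with the best mean CV AUC
is retained, until the requested number of features is reached.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import metrics
from .datasets import NEGATIVE, LabeledDataset
from .exceptions import ConfigError


@dataclass
class ScalerState:
    """Per-feature location (mean) and scale (population sd, ddof 0).

    Constant features get scale 1 (and a warning at fit time) so they map to
    exact zeros instead of dividing by zero.
    """

    location: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.location) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.location


def fit_standardizer(train: np.ndarray) -> ScalerState:
    """Fit mean/sd scaling on training rows (call on target-class data only)."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ConfigError("standardizer needs a non-empty 2-D matrix")
    location = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    constant = scale == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s); scale set to 1"
        )
        scale = np.where(constant, 1.0, scale)
    return ScalerState(location=location, scale=scale)


@dataclass
class SelectionTrace:
    """Greedy selection path: feature indices in the order they were kept."""

    selected: list[int]
    best_scores: list[float]
    evaluator: str = "auc"
    score_history: list[dict[int, float]] = field(default_factory=list)


def _centroid_scorer(X_train: np.ndarray, y_train: np.ndarray,
                     X_val: np.ndarray) -> np.ndarray:
    """Distance to the target-class centroid: larger = more positive-looking.

    A deliberately minimal reference classifier for selection: fast, convex,
    parameter-free, and consistent with the toolkit's distance-based view.
    """
    target = X_train[y_train == NEGATIVE]
    if target.shape[0] == 0:  # no target rows in fold: fall back to all rows
        target = X_train
    centroid = target.mean(axis=0)
    return np.linalg.norm(X_val - centroid, axis=1)


def _cv_auc(dataset: LabeledDataset, feature_idx: list[int], folds: int,
            seed: int, scorer) -> float:
    X = dataset.features[:, feature_idx]
    y = dataset.labels
    y_bin = (y == NEGATIVE).astype(int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, va in skf.split(X, y_bin):
        scaler = fit_standardizer(X[tr])
        scores = scorer(scaler.transform(X[tr]), y[tr], scaler.transform(X[va]))
        a = metrics.auc(y[va], scores, higher_is_positive=True)
        if a is not None:
            aucs.append(a)
    return float(np.mean(aucs)) if aucs else float("nan")


def stepwise_select(dataset: LabeledDataset, n_keep: int, folds: int = 5,
                    seed: int = 0, evaluator: str = "auc",
                    scorer=None, early_stop: bool = False) -> SelectionTrace:
    """Greedy forward selection by cross-validated AUC.

    Each round evaluates every remaining feature together with the kept set
    under stratified K-fold CV of a reference classifier (default: distance
    to the target-class centroid) and keeps the argmax-AUC feature; ties
    break toward the lowest feature index. Runs to ``n_keep`` features even
    if the score drops, unless ``early_stop`` is set.
    """
    if evaluator != "auc":
        raise ConfigError(f"unsupported evaluator {evaluator!r}")
    d = dataset.n_features
    if not 1 <= n_keep <= d:
        raise ConfigError(f"n_keep must lie in [1, {d}], got {n_keep}")
    if scorer is None:
        scorer = _centroid_scorer

    selected: list[int] = []
    best_scores: list[float] = []
    history: list[dict[int, float]] = []
    while len(selected) < n_keep:
        round_scores: dict[int, float] = {}
        for f in range(d):
            if f in selected:
                continue
            round_scores[f] = _cv_auc(dataset, selected + [f], folds, seed, scorer)
        # argmax with lowest-index tie-break; NaN (no defined fold) ranks last
        def _key(f: int):
            s = round_scores[f]
            return (s if not np.isnan(s) else -np.inf, -f)
        best_f = max(round_scores, key=_key)
        if early_stop and best_scores and round_scores[best_f] < best_scores[-1]:
            break
        selected.append(best_f)
        best_scores.append(round_scores[best_f])
        history.append(round_scores)
    return SelectionTrace(selected=selected, best_scores=best_scores,
                          evaluator=evaluator, score_history=history)
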