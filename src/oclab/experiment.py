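"""Cross-validated evaluation harnesses for one-class methods and baselines.

Protocol: ``rounds`` repetitions of a seeded stratified ``outer_folds``-fold
split. In each fold the one-class methods see only the majority (negative /
target) training rows; proxy outliers are detected inside that target set
(IQR fence for the plain variants, KMOR for the "-kmor" variants) and used
to tune (J, K) and/or theta by stratified inner CV; the fitted model is then
evaluated on the held-out mixed fold. Supervised baselines run under the
identical split protocol but train on the full (two-class) training fold.

Aggregation pools the per-(round, fold) metrics flat and reports the mean
and sample standard deviation per metric; folds where a metric is undefined
(e.g. no positives ended up in the fold) are excluded from that metric's
mean, with the exclusion count reported.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC, OneClassSVM

from . import metrics
from .datasets import NEGATIVE, POSITIVE, LabeledDataset
from .exceptions import ConfigError
from .kmor import KMORConfig
from .lbnn import lbnn_classify, lbnn_fit, lbnn_scores
from .ocnn import NON_TARGET, OCNN
from .preprocessing import fit_standardizer
from .tuning import (PROXY_OUTLIER, build_proxy_dataset, optimize_jk,
                     optimize_theta)

logger = logging.getLogger(__name__)

ONE_CLASS_METHODS = ("11nn", "11nn_theta", "jknn", "11nn_theta_kmor",
                     "jknn_kmor", "lbnn")
BASELINE_METHODS = ("ocsvm", "logreg", "svm", "rf")
METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "gmeans", "auc")


@dataclass
class ExperimentConfig:
    """Full harness configuration (defaults match the reference protocol:
    5 outer folds, 2 inner folds, 10 rounds, n0 = 0.05 n, gamma 2.5,
    itermax 100, theta = 1 for JKNN variants, OC-SVM nu = 0.5)."""

    method: str = "lbnn"
    outer_folds: int = 5
    inner_folds: int = 2
    rounds: int = 10
    seed: int = 0
    standardize: bool = True
    theta_fallback: float = 1.5       # fixed theta when the scan is degenerate
    jk_J_values: list[int] = field(default_factory=lambda: list(range(1, 11)))
    jk_K_values: list[int] = field(default_factory=lambda: list(range(1, 11)))
    kmor_gamma: float = 2.5
    kmor_n0_fraction: float = 0.05
    kmor_itermax: int = 100
    kmor_k: int = 1
    # cluster counts tried (min objective wins) for both the KMOR proxy
    # detector and LBNN's clustering stage
    kmor_k_candidates: list[int] = field(default_factory=lambda: [1, 2, 3])
    lbnn_Q: float = 0.9
    ocsvm_nu: float = 0.5

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in ONE_CLASS_METHODS + BASELINE_METHODS:
            raise ConfigError(
                f"unknown method {self.method!r}; choose from "
                f"{ONE_CLASS_METHODS + BASELINE_METHODS}"
            )
        if self.outer_folds < 2 or self.rounds < 1:
            raise ConfigError("need outer_folds >= 2 and rounds >= 1")

    def kmor_config(self, seed: int) -> KMORConfig:
        return KMORConfig(k=self.kmor_k, gamma=self.kmor_gamma,
                          n0_fraction=self.kmor_n0_fraction,
                          itermax=self.kmor_itermax, seed=seed)


@dataclass
class AggregateStat:
    mean: float | None
    std: float | None
    n_used: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {"mean": self.mean, "std": self.std,
                "n_used": self.n_used, "n_excluded": self.n_excluded}


@dataclass
class RunRecord:
    """All per-fold reports of one experiment plus pooled aggregates."""

    method: str
    dataset_name: str
    seed: int
    fold_reports: list[tuple[int, int, metrics.EvaluationReport]]
    aggregates: dict[str, AggregateStat]
    n_skipped_folds: int
    config: ExperimentConfig

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "dataset": self.dataset_name,
            "seed": self.seed,
            "aggregates": {k: v.to_dict() for k, v in self.aggregates.items()},
            "n_skipped_folds": self.n_skipped_folds,
            "folds": [
                {"round": r, "fold": f, **rep.to_dict()}
                for r, f, rep in self.fold_reports
            ],
            "config": {
                "outer_folds": self.config.outer_folds,
                "inner_folds": self.config.inner_folds,
                "rounds": self.config.rounds,
                "standardize": self.config.standardize,
            },
        }


def _aggregate(fold_reports, method, dataset_name, seed, config,
               n_skipped) -> RunRecord:
    aggregates = {}
    for name in METRIC_NAMES:
        values = [getattr(rep, name) for _, _, rep in fold_reports]
        defined = [v for v in values if v is not None]
        if defined:
            mean = float(np.mean(defined))
            std = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        else:
            mean = std = None
        aggregates[name] = AggregateStat(mean=mean, std=std, n_used=len(defined),
                                         n_excluded=len(values) - len(defined))
    return RunRecord(method=method, dataset_name=dataset_name, seed=seed,
                     fold_reports=fold_reports, aggregates=aggregates,
                     n_skipped_folds=n_skipped, config=config)


def _outer_splits(dataset: LabeledDataset, config: ExperimentConfig):
    """Yield (round, fold, train_idx, test_idx); stratified and seeded."""
    y = (dataset.labels == POSITIVE).astype(int)
    round_seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=config.rounds
    )
    min_class = min(int(y.sum()), int(len(y) - y.sum()))
    stratified = config.outer_folds <= min_class
    if not stratified:
        logger.warning(
            "outer_folds=%d exceeds the smaller class count %d; "
            "falling back to unstratified folds", config.outer_folds, min_class
        )
    for r in range(config.rounds):
        if stratified:
            splitter = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                                       random_state=int(round_seeds[r]))
        else:
            splitter = KFold(n_splits=config.outer_folds, shuffle=True,
                             random_state=int(round_seeds[r]))
        for f, (tr, te) in enumerate(splitter.split(dataset.features, y)):
            yield r, f, tr, te


def _evaluate_fold(y_test, pred_positive, scores_positive) -> metrics.EvaluationReport:
    y_pred = np.where(pred_positive, POSITIVE, NEGATIVE).astype(object)
    report = metrics.compute_metrics(metrics.confusion(y_test, y_pred))
    report.auc = metrics.auc(y_test, scores_positive, higher_is_positive=True)
    return report


def _fit_score_ocnn(X_target, X_test, method: str, config: ExperimentConfig,
                    fold_seed: int):
    """Tune on proxy outliers as the variant dictates, fit, score the fold."""
    detector = "kmor" if method.endswith("_kmor") else "iqr"
    proxy = build_proxy_dataset(X_target, method=detector,
                                kmor_config=config.kmor_config(fold_seed),
                                k_candidates=config.kmor_k_candidates)
    J = K = 1
    theta = 1.0
    if method in ("jknn", "jknn_kmor"):
        J, K, _ = optimize_jk(proxy, config.jk_J_values, config.jk_K_values,
                              inner_folds=config.inner_folds, seed=fold_seed)
    elif method in ("11nn_theta", "11nn_theta_kmor"):
        scan = optimize_theta(proxy, inner_folds=config.inner_folds,
                              seed=fold_seed,
                              theta_fallback=config.theta_fallback)
        theta = scan.theta_best
    # The final model learns the cleaned target class: detected outliers are
    # noise by assumption and would otherwise anchor spurious neighborhoods.
    X_clean = X_target[proxy.proxy_labels != PROXY_OUTLIER]
    if X_clean.shape[0] < J + K:
        X_clean = X_target
    model = OCNN(J=J, K=K, theta=theta, standardize=False).fit(X_clean)
    scores = model.score(X_test)
    pred_positive = ~(scores < theta)  # non-target => positive
    return pred_positive, scores


def run_ocnn_experiment(dataset: LabeledDataset,
                        config: ExperimentConfig) -> RunRecord:
    """Evaluate an OCNN variant under the outer-CV protocol."""
    if config.method not in ("11nn", "11nn_theta", "jknn",
                             "11nn_theta_kmor", "jknn_kmor"):
        raise ConfigError(f"{config.method!r} is not an OCNN variant")
    return _run_one_class(dataset, config, _fit_score_ocnn)


def run_lbnn_experiment(dataset: LabeledDataset,
                        config: ExperimentConfig) -> RunRecord:
    """Evaluate LBNN (KMOR clustering + percentile rule) under the protocol."""

    def fit_score(X_target, X_test, method, cfg, fold_seed):
        model = lbnn_fit(
            X_target,
            kmor_config=cfg.kmor_config(fold_seed),
            Q=cfg.lbnn_Q,
            k_candidates=cfg.kmor_k_candidates,
            standardize=False,
        )
        accepted = lbnn_classify(model, X_test)
        scores = lbnn_scores(model, X_test)
        return accepted == 0, scores

    cfg = replace(config, method="lbnn") if config.method != "lbnn" else config
    return _run_one_class(dataset, cfg, fit_score)


def _run_one_class(dataset, config, fit_score) -> RunRecord:
    fold_reports = []
    n_skipped = 0
    for r, f, tr, te in _outer_splits(dataset, config):
        t0 = time.perf_counter()
        y_test = dataset.labels[te]
        if not np.any(y_test == POSITIVE):
            logger.warning("round %d fold %d has no positives; skipped", r, f)
            n_skipped += 1
            continue
        target_mask = dataset.labels[tr] == NEGATIVE
        X_target = dataset.features[tr][target_mask]
        X_test = dataset.features[te]
        if config.standardize:
            scaler = fit_standardizer(X_target)
            X_target = scaler.transform(X_target)
            X_test = scaler.transform(X_test)
        fold_seed = int((config.seed * 7919 + r * 613 + f) % (2**31 - 1))
        pred_positive, scores = fit_score(X_target, X_test, config.method,
                                          config, fold_seed)
        fold_reports.append((r, f, _evaluate_fold(y_test, pred_positive, scores)))
        logger.debug("round %d fold %d done in %.2fs", r, f,
                     time.perf_counter() - t0)
    return _aggregate(fold_reports, config.method, dataset.name, config.seed,
                      config, n_skipped)


def run_baselines(dataset: LabeledDataset, config: ExperimentConfig) -> RunRecord:
    """Wrapped scikit-learn baselines under the identical split protocol.

    These are deliberately thin wrappers (not re-implementations): OC-SVM
    (nu = 0.5, RBF with kernel coefficient 1/d) trained on target rows only;
    logistic regression, RBF-SVM (small C grid) and random forest trained on
    the full two-class training fold.
    """
    method = config.method
    if method not in BASELINE_METHODS:
        raise ConfigError(f"{method!r} is not a baseline method")
    fold_reports = []
    n_skipped = 0
    d = dataset.n_features
    for r, f, tr, te in _outer_splits(dataset, config):
        y_test = dataset.labels[te]
        if not np.any(y_test == POSITIVE):
            n_skipped += 1
            continue
        fold_seed = int((config.seed * 7919 + r * 613 + f) % (2**31 - 1))
        X_tr, y_tr = dataset.features[tr], dataset.labels[tr]
        X_te = dataset.features[te]
        if method == "ocsvm":
            target = X_tr[y_tr == NEGATIVE]
            scaler = fit_standardizer(target) if config.standardize else None
            if scaler:
                target, X_eval = scaler.transform(target), scaler.transform(X_te)
            else:
                X_eval = X_te
            model = OneClassSVM(nu=config.ocsvm_nu, kernel="rbf", gamma=1.0 / d)
            model.fit(target)
            dec = model.decision_function(X_eval)  # >0 = inlier/target
            pred_positive = dec < 0
            scores = -dec
        else:
            scaler = fit_standardizer(X_tr) if config.standardize else None
            if scaler:
                X_fit, X_eval = scaler.transform(X_tr), scaler.transform(X_te)
            else:
                X_fit, X_eval = X_tr, X_te
            y_fit = (y_tr == POSITIVE).astype(int)
            if y_fit.sum() == 0 or y_fit.sum() == len(y_fit):
                logger.warning("training fold single-class; skipped")
                n_skipped += 1
                continue
            if method == "logreg":
                model = LogisticRegression(max_iter=1000)
            elif method == "svm":
                inner = min(config.inner_folds, int(y_fit.sum()))
                svc = SVC(kernel="rbf", gamma="scale", probability=False)
                if inner >= 2:
                    model = GridSearchCV(svc, {"C": [1.0, 10.0, 100.0]},
                                         cv=StratifiedKFold(inner, shuffle=True,
                                                            random_state=fold_seed),
                                         scoring="roc_auc")
                else:
                    model = svc
            else:  # rf
                model = RandomForestClassifier(n_estimators=200,
                                               random_state=fold_seed)
            model.fit(X_fit, y_fit)
            if hasattr(model, "predict_proba"):
                scores = model.predict_proba(X_eval)[:, 1]
            else:
                scores = model.decision_function(X_eval)
            pred_positive = model.predict(X_eval) == 1
        fold_reports.append((r, f, _evaluate_fold(y_test, pred_positive, scores)))
    return _aggregate(fold_reports, method, dataset.name, config.seed,
                      config, n_skipped)


def run_experiment(dataset: LabeledDataset, config: ExperimentConfig) -> RunRecord:
    """Dispatch on ``config.method``."""
    if config.method == "lbnn":
        return run_lbnn_experiment(dataset, config)
    if config.method in BASELINE_METHODS:
        return run_baselines(dataset, config)
    return run_ocnn_experiment(dataset, config)
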