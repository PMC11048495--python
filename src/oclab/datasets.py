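"""Core dataset containers.

The whole toolkit works on :class:`LabeledDataset`: a dense numeric feature
matrix plus a binary label vector using the imbalanced-learning convention
that ``positive`` is the minority / non-target class (the class a one-class
classifier must flag) and ``negative`` is the majority / target class (the
only class seen at one-class training time).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, SummaryError

#: Label of the minority / non-target class.
POSITIVE = "positive"
#: Label of the majority / target class.
NEGATIVE = "negative"


@dataclass
class LabeledDataset:
    """A numeric feature matrix with binary labels.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Dense float matrix; no missing values.
    labels : ndarray of shape (n_samples,)
        String labels, each either ``"positive"`` or ``"negative"``.
    feature_names : list of str
        One name per column.
    name : str
        Dataset identifier used in reports.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ConfigError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ConfigError("dataset needs at least one row and one feature")
        if self.labels.shape != (n,):
            raise ConfigError(
                f"labels length {self.labels.shape} does not match {n} rows"
            )
        bad = set(np.unique(self.labels)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ConfigError(f"unknown label values: {sorted(map(str, bad))}")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(d)]
        if len(self.feature_names) != d:
            raise ConfigError("feature_names length does not match n_features")
        if not np.isfinite(self.features).all():
            raise ConfigError("features contain NaN or infinite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def positive_mask(self) -> np.ndarray:
        return self.labels == POSITIVE

    def target_features(self) -> np.ndarray:
        """Rows of the majority (target / negative) class only."""
        return self.features[self.labels == NEGATIVE]


@dataclass(frozen=True)
class DatasetSummary:
    """Class-balance summary of a :class:`LabeledDataset`.

    ``imbalance_ratio`` is the majority count divided by the minority count,
    kept as an unrounded real; presentation layers round to two decimals.
    """

    n_features: int
    n_samples: int
    n_minority: int
    n_majority: int
    imbalance_ratio: float


def summarize(dataset: LabeledDataset) -> DatasetSummary:
    """Count classes and compute the imbalance ratio (majority / minority).

    Raises
    ------
    SummaryError
        If either class is absent (the ratio is then undefined).
    """
    n_min = int(np.sum(dataset.labels == POSITIVE))
    n_maj = int(np.sum(dataset.labels == NEGATIVE))
    if n_min == 0 or n_maj == 0:
        raise SummaryError(
            "imbalance ratio undefined: dataset does not contain both classes"
        )
    return DatasetSummary(
        n_features=dataset.n_features,
        n_samples=dataset.n_samples,
        n_minority=n_min,
        n_majority=n_maj,
        imbalance_ratio=n_maj / n_min,
    )
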