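"""Seeded generator of imbalanced, clustered, outlier-contaminated data.

Emulates the structure of the imbalanced benchmarks the toolkit targets: a
majority ("negative") target class drawn from a mixture of well-separated
isotropic Gaussian clusters, a small fraction of target points displaced far
from their cluster (planted outliers, e.g. mislabeled or noisy records), and
a minority ("positive") class shifted away from the target mass. Every draw
is fully determined by the spec's seed, and the ground truth (cluster ids,
outlier flags) is returned alongside so detection and recovery can be
asserted exactly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .datasets import NEGATIVE, POSITIVE, LabeledDataset
from .exceptions import ConfigError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Distances (``cluster_separation``, ``outlier_distance``,
    ``minority_offset``) are expressed in units of ``cluster_sd`` so that
    "a 10-sigma outlier" reads literally.
    """

    n_target: int = 200
    n_minority: int = 20
    n_features: int = 2
    n_clusters: int = 1
    cluster_sd: float = 1.0
    cluster_separation: float = 10.0
    outlier_fraction: float = 0.0
    outlier_distance: float = 10.0
    minority_offset: float = 10.0
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ConfigError("n_target must be >= 1")
        if self.n_minority < 0:
            raise ConfigError("n_minority must be >= 0")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.n_clusters > 1 and self.n_features < self.n_clusters:
            raise ConfigError(
                "need n_features >= n_clusters to place simplex centers"
            )
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ConfigError("outlier_fraction must lie in [0, 1)")
        if self.cluster_sd <= 0:
            raise ConfigError("cluster_sd must be positive")
        if self.n_target < self.n_clusters:
            raise ConfigError("n_target must be >= n_clusters")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth aligned row-by-row with the generated dataset.

    ``cluster_ids`` holds 0..k-1 for target rows and -1 for minority rows;
    ``outlier_flags`` marks the planted target-class outliers.
    """

    cluster_ids: np.ndarray
    outlier_flags: np.ndarray
    centers: np.ndarray
    minority_center: np.ndarray


def _cluster_centers(spec: SyntheticSpec) -> np.ndarray:
    """Centers on a regular simplex with pairwise distance separation*sd."""
    k, d = spec.n_clusters, spec.n_features
    if k == 1:
        return np.zeros((1, d))
    # Scaled identity vertices: |e_i - e_j| = sqrt(2), so scale accordingly.
    scale = spec.cluster_separation * spec.cluster_sd / np.sqrt(2.0)
    centers = np.zeros((k, d))
    centers[:, :k] = np.eye(k) * scale
    return centers


def _offset_direction(centers: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A unit vector orthogonal to the span of the centered cluster centers.

    Guarantees the minority center is at least ``minority_offset`` sd from
    every cluster center. Falls back to a random unit vector when no
    orthogonal direction exists.
    """
    d = centers.shape[1]
    centered = centers - centers.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=True)
    rank = int(np.sum(s > 1e-9)) if s.size else 0
    if rank < d:
        return vt[-1]
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, SyntheticTruth]:
    """Draw one dataset according to ``spec``; deterministic given its seed.

    Target rows come first (grouped by cluster), minority rows last. Exactly
    ``floor(outlier_fraction * n_target)`` target rows are replaced by points
    at ``outlier_distance * cluster_sd`` from their cluster center along a
    random direction, and flagged in the returned truth.
    """
    rng = np.random.default_rng(spec.seed)
    k, d, sd = spec.n_clusters, spec.n_features, spec.cluster_sd
    centers = _cluster_centers(spec)

    # Split the target count as evenly as possible across clusters.
    base, extra = divmod(spec.n_target, k)
    sizes = [base + (1 if i < extra else 0) for i in range(k)]

    rows, cluster_ids = [], []
    for c, size in enumerate(sizes):
        rows.append(centers[c] + sd * rng.standard_normal((size, d)))
        cluster_ids.extend([c] * size)
    X_target = np.vstack(rows)
    cluster_ids = np.asarray(cluster_ids)

    n_out = int(np.floor(spec.outlier_fraction * spec.n_target))
    outlier_flags = np.zeros(spec.n_target, dtype=bool)
    if n_out > 0:
        idx = rng.choice(spec.n_target, size=n_out, replace=False)
        for i in idx:
            direction = rng.standard_normal(d)
            direction /= np.linalg.norm(direction)
            X_target[i] = centers[cluster_ids[i]] + spec.outlier_distance * sd * direction
        outlier_flags[idx] = True

    minority_center = centers.mean(axis=0) + (
        spec.minority_offset * sd * _offset_direction(centers, rng)
    )
    if spec.n_minority > 0:
        X_min = minority_center + sd * rng.standard_normal((spec.n_minority, d))
        features = np.vstack([X_target, X_min])
    else:
        features = X_target

    labels = np.array(
        [NEGATIVE] * spec.n_target + [POSITIVE] * spec.n_minority, dtype=object
    )
    dataset = LabeledDataset(
        features=features,
        labels=labels,
        feature_names=[f"f{i}" for i in range(d)],
        name=spec.name,
    )
    truth = SyntheticTruth(
        cluster_ids=np.concatenate([cluster_ids, -np.ones(spec.n_minority, dtype=int)]),
        outlier_flags=np.concatenate(
            [outlier_flags, np.zeros(spec.n_minority, dtype=bool)]
        ),
        centers=centers,
        minority_center=minority_center,
    )
    return dataset, truth


#: Named study conditions reused across tests and the CLI.
PRESETS: dict[str, SyntheticSpec] = {
    # One tight unit-sd blob with 5% of points planted at 10 sigma: the
    # canonical proxy-outlier construction for parameter tuning.
    "blob-outliers": SyntheticSpec(
        n_target=100, n_minority=0, n_features=2, n_clusters=1,
        cluster_sd=1.0, outlier_fraction=0.05, outlier_distance=10.0,
        seed=0, name="blob-outliers",
    ),
    # Two tight blobs (sd 0.2) whose centers sit 10 apart (50 sd): the
    # cluster-count selection / LBNN fitting construction.
    "two-blobs": SyntheticSpec(
        n_target=100, n_minority=0, n_features=2, n_clusters=2,
        cluster_sd=0.2, cluster_separation=50.0, outlier_fraction=0.0,
        seed=0, name="two-blobs",
    ),
    # Fully separable end-to-end condition: two unit-sd target clusters 10
    # sigma apart, minority class offset 10 sigma, 300 rows total.
    "separable": SyntheticSpec(
        n_target=250, n_minority=50, n_features=2, n_clusters=2,
        cluster_sd=1.0, cluster_separation=10.0, outlier_fraction=0.0,
        minority_offset=10.0, seed=0, name="separable",
    ),
}


def preset(name: str, seed: int | None = None, **overrides) -> SyntheticSpec:
    """Fetch a preset by name, optionally replacing the seed or any field."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        overrides["seed"] = seed
    return dataclasses.replace(spec, **overrides) if overrides else spec
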