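# Methods

This note records the models implemented in `oclab`, their assumptions, the
parameter choices that matter, and the points where the design was genuinely
open and a decision had to be made. It states no empirical claim that the
test suite does not itself compute.

## Problem setting

A binary dataset with labels `positive` (minority, non-target — e.g. the
patients to flag) and `negative` (majority, target). One-class classifiers
train on target rows only and must decide, for an unseen point, whether it
belongs to the target class. The headline metric is G-means,
`√(recall · specificity)`, because on imbalanced data accuracy is dominated
by the majority class while G-means is high only when both classes are
recognised. All undefined metrics (zero denominators, single-class folds)
are reported as explicit nulls, never NaN arithmetic; published tables are
matched by *truncation* to their printed precision, and nothing is rounded
internally.

## OCNN

`score(z) = D_J / D_K` with Euclidean distances; accept iff `score < θ`
(strict). `D_J` is the mean distance from `z` to its `J` nearest training
rows; `D_K` the mean distance from each of those neighbors to its own `K`
nearest training rows, **excluding the neighbor itself** — a distance-0
self-match would zero `D_K`. First-stage queries over an external test point
use all training rows. Ties in neighbor search break toward the lowest row
index, making every result reproducible.

Degenerate cases are defined, not accidental: `D_J = 0` (test point
coincides with a training row) scores 0 and is accepted for any θ > 0;
`D_K = 0` with `D_J > 0` (duplicated training rows) scores +∞ and is
rejected for any finite θ. Search is exact and vectorized (full distance
matrices); at the intended desk scale (hundreds to a few thousand rows)
approximate neighbor indices would add complexity without measurable
benefit, and the family's two-stage structure keeps per-query cost linear
in the training size.

## KMOR

Objective and update rules as in the README. Numerical choices:

- Distances inside the objective are **squared** Euclidean; the reported
  outlier threshold `d_threshold_final` is in squared units.
- Rule 1 uses the threshold `D(U, Z)` computed from the *current*
  assignment and centers before re-assigning; the first sweep's threshold
  comes from the initial no-outlier nearest-center assignment. A point
  becomes an outlier when its nearest-center squared distance strictly
  exceeds the threshold.
- The printed rules contain no mechanism enforcing the `n0` cap. Decision:
  if more points qualify than `n0`, keep the `n0` largest-distance ones as
  outliers and assign the rest to their nearest centers (greedy enforcement
  that preserves the objective's structure). The result records whether the
  cap bound (`cap_hit`), since capped runs may leave qualifying points
  inside regular clusters.
- Empty clusters after Rule 2 are re-seeded with the farthest current
  non-outlier point (standard K-means repair; keeps k constant).
- Convergence: absolute objective change below `delta = 1e-6` (well below
  any meaningful change at this data scale) or `itermax = 100` sweeps.
- γ (`gamma`, reported as λ = 2.5 in the reference configuration) weights
  the average inlier distance in the threshold; `n0 = floor(0.05 · n)` by
  default. Both are exposed per run.
- **Restarts.** Initialization samples k distinct rows. A single random
  start is vulnerable to a specific local minimum: a far outlier drawn as
  an initial center anchors its own cluster and can never be removed (on
  the line `{0, 1, 10, 11, 100}` with k = 2 this traps the fit at
  P ≈ 98.6 versus the global 1.625). `kmor_fit` therefore keeps the best
  of `n_restarts = 5` seeded starts; `n_restarts = 1` recovers the bare
  single-start sweep, which is what the Lloyd-equivalence tests instrument
  (with `n0 = 0` the sweep is exactly Lloyd's algorithm from the shared
  initialization).
- **Cluster-count selection** takes an explicit candidate list and returns
  the argmin of the final objective (ties toward smaller k). The objective,
  like plain K-means SSE, decreases as k grows, so min-objective selection
  effectively prefers the largest candidate; this is an inherited property
  of the selection rule, which is why candidates must be a deliberate,
  bounded list and the full objective-vs-k curve is returned for
  inspection. No penalty term is invented.

## Proxy-outlier tuning

Detectors. The IQR detector computes each training point's distance to its
nearest *other* point and flags those beyond `Q3 + 1.5·IQR` of that
distance distribution (quartiles by linear interpolation). Distance-based
fences are used rather than per-feature fences because marginal extremes
need not be distance outliers, and the distance view matches the
classifiers being tuned. Documented blind spot: a tight pair of far-away
points gives both members a near-zero 1-NN distance, so neither is flagged.
The fence also has no count cap, so on a plain Gaussian cloud it flags the
natural fringe along with any planted noise. The KMOR detector (outlier
cluster of a fit, optionally with cluster-count selection first) caps its
flags at `n0` largest distances and is the tighter of the two.

`optimize_jk` runs stratified inner CV (default 2 folds; stratification on
{target, proxy} is essential because proxy counts are tiny) over a
`{1..10} × {1..10}` grid; each fold fits JKNN at θ = 1 on the fold's
target-labeled rows and scores the held-out mix by G-means. Cells
infeasible for the smallest training fold (J + K too large) are excluded.
Ties break toward the smallest J, then K.

`optimize_theta` collects, for every validation point, the candidate
θ = D1/D11 (its 1-NN distance against the fold's target-only training part
divided by that neighbor's own 1-NN distance). Because the 11NN score of a
validation point *is* this ratio, each candidate is evaluated by
thresholding the pooled per-fold scores with the same folds and averaging
fold G-means; ties break toward the smallest θ. Candidates with `D11 = 0`
are skipped. If detection finds no outliers or no candidate is usable, a
configurable fallback θ (default 1.5, exposed as `theta_fallback`) is
returned with a warning rather than silently fabricating a scan.

The experiment harness fits the final model on the *cleaned* target data —
detected outliers removed — since they are noise by assumption and would
otherwise anchor spurious neighborhoods (it falls back to the full target
set only if cleaning leaves fewer than J + K rows).

## LBNN

Fit: KMOR-cluster the target class (fixed k or min-objective selection over
candidates), drop outlier-cluster members (they are by construction
non-representative and never serve as reference points), and precompute for
every remaining member the Q-th percentile of its distances to the other
members of its cluster. Clusters reduced to a single member are merged into
the cluster with the nearest center, because a singleton has no
within-cluster distances and its threshold would be undefined.

Classify: per test point, scan clusters in index order; the nearest member
of cluster c is the reference; accept on the first cluster where the
reference distance is strictly below the reference's percentile threshold.
The percentile uses linear interpolation between order statistics
(rank `Q·(m−1)`), so Q = 0 is the minimum and Q = 1 the maximum, and the
accepted set is non-decreasing in Q.

The continuous score `min_c d_c / threshold_c` (with +∞ when a threshold is
zero) satisfies `score < 1 ⟺ accepted` regardless of scan order and serves
as the AUC statistic. Q has no canonical value; the default is 0.9 (accept
within the bulk of a reference's neighborhood while keeping a 10% guard
band), exposed as `lbnn_Q`, with an optional proxy-based tuner scanning a
Q grid by G-means for users who prefer data-driven choice.

## Standardization

All distance-based estimators standardize by default (per-feature mean/sd,
population ddof 0, fit on the training target class only; constant features
get scale 1 with a warning). The harness applies one scaler per fold and
constructs estimators with internal scaling off to avoid double
transformation. Scaling matters because Euclidean distances are otherwise
dominated by large-variance features.

## Stepwise feature selection

Greedy forward selection scored by stratified-CV AUC of a reference
classifier; each round tries every remaining feature jointly with the kept
set and keeps the argmax (ties toward the lowest index), running to the
requested count even if the score drops (optional early stop). The
reference classifier is deliberately minimal — distance to the target-class
centroid — so selection stays fast, deterministic and free of heavyweight
model dependencies; it is injectable for users who want a different scorer.

## Evaluation harness

Default protocol: 10 rounds × 5 stratified outer folds (2 inner folds for
tuning), seeded throughout; one-class methods see only negative training
rows (asserted by instrumentation in the tests). When the requested fold
count exceeds the smaller class count, the split falls back to unstratified
K-fold with a warning so leave-one-out-style runs remain possible. Folds
whose test part has no positives are skipped and counted. Aggregation pools
all per-(round, fold) metrics flat and reports mean and sample standard
deviation per metric, with per-metric exclusion counts for undefined folds.
Baselines are thin scikit-learn wrappers under the identical protocol:
one-class SVM (ν = 0.5, RBF, kernel coefficient 1/d) trained on target rows
only; logistic regression, RBF-SVM (small inner-CV grid over
C ∈ {1, 10, 100} — the reference configuration names grid search without a
grid) and random forest trained on the full two-class fold.

## Synthetic data: what it emulates and what it does not

The generator draws the target class from k isotropic Gaussian clusters
with centers on a regular simplex (pairwise distance
`cluster_separation · cluster_sd`), replaces a fixed fraction of target
rows with points planted at `outlier_distance · cluster_sd` from their
cluster center (ground-truth flagged), and draws the minority class from a
Gaussian displaced `minority_offset · cluster_sd` from the target centroid
along a direction orthogonal to the span of the cluster centers — so the
minority is at least the stated offset from *every* cluster center. All
draws are deterministic given the seed.

Named presets fix the study conditions used throughout the tests:
`blob-outliers` (one unit-sd blob of 100 with five 10σ planted outliers —
the canonical proxy-tuning construction), `two-blobs` (two sd-0.2 blobs 10
apart — cluster-count and LBNN fitting), and `separable` (two unit-sd
target clusters 10σ apart, 250 target + 50 minority rows at 10σ offset —
the end-to-end condition).

What passing tests on these data do **not** show: real medical tables have
correlated, heterogeneous, sometimes near-discrete features; class overlap
rather than clean 10σ margins; and label noise that is not radially
symmetric. Results on the presets certify algorithmic correctness and
recovery under known ground truth, not clinical performance.

## Known limitations

- Min-objective cluster-count selection degenerates to "largest candidate"
  as discussed above; users should treat the candidate list as a prior.
- The IQR detector is blind to tight groups of duplicated outliers.
- Proxy-outlier tuning optimizes separation of *detected* fringe points,
  which on clean data is a systematically stricter criterion than the
  unknown true-negative boundary; tuned JKNN therefore tends to sacrifice
  some specificity (visible in the README's worked example, where
  `jknn_kmor` reaches G-means ≈ 0.91 against LBNN's 1.0).
- Every model is a lazy learner: predictions rescan the stored training
  data, and there is no online update path.
- Test-suite problem sizes (hundreds of rows, ≤ 10 features, 100-trial
  property sweeps) were chosen so the full suite completes in seconds while
  still exercising every degenerate branch.
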