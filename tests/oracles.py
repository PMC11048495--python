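"""Independent reference implementations used as test oracles.

Everything here is deliberately written in a different style (explicit
loops, exhaustive enumeration) from the library code it checks.
"""
import itertools

import numpy as np

from oclab.kmor import OUTLIER_LABEL


def brute_force_auc(y_true, scores, positive="positive"):
    """Pair-counting AUC: P(score_pos > score_neg) with ties at 0.5."""
    pos = [s for y, s in zip(y_true, scores) if y == positive]
    neg = [s for y, s in zip(y_true, scores) if y != positive]
    total = wins = 0
    for sp in pos:
        for sn in neg:
            total += 1
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / total


def percentile_oracle(values, Q):
    """Sort-and-index interpolation between order statistics."""
    v = sorted(values)
    r = Q * (len(v) - 1)
    lo, hi = int(np.floor(r)), int(np.ceil(r))
    return v[lo] + (r - lo) * (v[hi] - v[lo])


def brute_force_ocnn_score(train, z, J, K):
    """Loop-based D_J/D_K reference with lowest-index tie-breaks."""
    n = len(train)
    by_dist = sorted(range(n),
                     key=lambda i: (float(np.linalg.norm(train[i] - z)), i))
    anchors = by_dist[:J]
    dj = np.mean([np.linalg.norm(train[i] - z) for i in anchors])
    dk_terms = []
    for a in anchors:
        others = sorted(
            (i for i in range(n) if i != a),
            key=lambda i: (float(np.linalg.norm(train[i] - train[a])), i))
        dk_terms.extend(np.linalg.norm(train[i] - train[a]) for i in others[:K])
    dk = np.mean(dk_terms)
    if dj == 0:
        return 0.0
    if dk == 0:
        return np.inf
    return dj / dk


def kmor_objective_oracle(X, assignments, centers, gamma):
    """Term-by-term objective summation in reversed order."""
    n = len(X)
    inliers = [i for i in range(n) if assignments[i] != OUTLIER_LABEL]
    sse = 0.0
    for i in reversed(inliers):
        sse += sum((X[i, d] - centers[assignments[i], d]) ** 2
                   for d in range(X.shape[1]))
    d_threshold = gamma * sse / len(inliers)
    return sse + (n - len(inliers)) * d_threshold


def enumerate_kmor_optimum(X, k, gamma, n0):
    """Global optimum by exhaustive assignment enumeration (tiny n only)."""
    n = len(X)
    best = (np.inf, None)
    labels = list(range(k)) + [OUTLIER_LABEL]
    for assign in itertools.product(labels, repeat=n):
        assign = np.asarray(assign)
        if np.sum(assign == OUTLIER_LABEL) > n0:
            continue
        if len({a for a in assign if a != OUTLIER_LABEL}) < k:
            continue
        centers = np.vstack([X[assign == j].mean(axis=0) for j in range(k)])
        p = kmor_objective_oracle(X, assign, centers, gamma)
        if p < best[0]:
            best = (p, assign)
    return best


def nearest_assign(X, centers):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def lloyd_history(X, init_centers, n_iter):
    """Plain Lloyd (assign step then mean update) iteration history."""
    centers = init_centers.copy()
    history = [(nearest_assign(X, centers), centers.copy())]
    for _ in range(n_iter):
        assign = nearest_assign(X, centers)
        for j in range(len(centers)):
            members = X[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
        history.append((assign.copy(), centers.copy()))
    return history
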