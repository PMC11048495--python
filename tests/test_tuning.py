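"""Proxy-outlier detection and (J, K) / theta optimization."""
import numpy as np
import pytest

from oclab import DegenerateInputError, KMORConfig
from oclab.ocnn import TARGET
from oclab.synthetic import generate, preset
from oclab.tuning import (PROXY_OUTLIER, build_proxy_dataset, iqr_outliers,
                          optimize_jk, optimize_q, optimize_theta)


class TestIQROutliers:
    def test_hand_computed_line_example(self):
        """{0,1,2,3,100}: 1-NN distances {1,1,1,1,97}, IQR=0, fence=1."""
        X = np.array([[0.0], [1.0], [2.0], [3.0], [100.0]])
        assert list(iqr_outliers(X)) == [4]

    def test_equally_spaced_grid_has_no_outliers(self):
        X = np.arange(10, dtype=float)[:, None]
        assert len(iqr_outliers(X)) == 0

    def test_tight_outlier_pair_is_invisible(self):
        """Documented blind spot: two coincident far points are each other's
        1-NN at distance ~0, so the fence never flags them."""
        X = np.vstack([np.arange(8, dtype=float)[:, None],
                       [[100.0], [100.0]]])
        flagged = iqr_outliers(X)
        assert 8 not in flagged and 9 not in flagged

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            iqr_outliers(np.zeros((3, 1)))


class TestBuildProxy:
    def test_kmor_detector_recovers_planted_outliers(self, blob_outliers):
        ds, truth = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="kmor",
                                    kmor_config=KMORConfig(k=1, seed=0))
        flagged = set(np.flatnonzero(proxy.proxy_labels == PROXY_OUTLIER))
        assert flagged == set(np.flatnonzero(truth.outlier_flags))

    def test_iqr_detector_covers_planted_outliers(self, blob_outliers):
        """The 1-NN fence flags every planted 10-sigma point; on a 2-D
        Gaussian blob it may additionally flag a few natural fringe points
        (the fence has no count cap, unlike KMOR's n0)."""
        ds, truth = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        flagged = set(np.flatnonzero(proxy.proxy_labels == PROXY_OUTLIER))
        assert set(np.flatnonzero(truth.outlier_flags)) <= flagged
        assert len(flagged) <= 15

    def test_no_outliers_warns_and_labels_all_target(self):
        X = np.arange(20, dtype=float)[:, None]
        with pytest.warns(UserWarning, match="no outliers"):
            proxy = build_proxy_dataset(X, method="iqr")
        assert proxy.n_proxy_outliers == 0
        assert np.all(proxy.proxy_labels == TARGET)


class TestOptimizeJK:
    def test_tuned_model_rejects_all_planted_proxies(self, blob_outliers):
        """The tuned (J, K) cell, refit on the cleaned targets with theta=1,
        rejects every 10-sigma proxy (perfect minority-side recall)."""
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="kmor",
                                    kmor_config=KMORConfig(k=1, seed=0))
        J, K, grid = optimize_jk(proxy, J_values=[1, 2, 3], K_values=[1, 2, 3],
                                 inner_folds=2, seed=0)
        assert np.nanmax(grid.score_matrix) <= 1.0
        from oclab.ocnn import OCNN
        clean = proxy.features[proxy.proxy_labels == TARGET]
        model = OCNN(J=J, K=K, theta=1.0, standardize=False).fit(clean)
        proxies = proxy.features[proxy.proxy_labels == PROXY_OUTLIER]
        assert np.all(model.score(proxies) >= 1.0)

    def test_returned_pair_is_argmax_of_score_matrix(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        J, K, grid = optimize_jk(proxy, inner_folds=2, seed=3)
        best = None
        for a, Jv in enumerate(grid.J_values):
            for b, Kv in enumerate(grid.K_values):
                s = grid.score_matrix[a, b]
                if not np.isnan(s) and (best is None or s > best[0]):
                    best = (s, Jv, Kv)
        assert (J, K) == (best[1], best[2])

    def test_single_cell_grid(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        J, K, _ = optimize_jk(proxy, J_values=[1], K_values=[1], seed=0)
        assert (J, K) == (1, 1)

    def test_tie_break_smallest_j_then_k(self, blob_outliers):
        """On the fully separable construction many cells tie at 1.0; the
        winner must be the lexicographically smallest (J, K)."""
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        J, K, grid = optimize_jk(proxy, J_values=[1, 2, 3], K_values=[1, 2, 3],
                                 inner_folds=2, seed=0)
        top = grid.score_matrix.max()
        ties = [(Jv, Kv) for a, Jv in enumerate(grid.J_values)
                for b, Kv in enumerate(grid.K_values)
                if grid.score_matrix[a, b] == top]
        assert (J, K) == min(ties)

    def test_infeasible_cells_are_nan(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        _, _, grid = optimize_jk(proxy, J_values=[40], K_values=[40],
                                 inner_folds=2, seed=0)
        assert np.isnan(grid.score_matrix).all()

    def test_no_proxies_returns_default_with_warning(self):
        X = np.arange(20, dtype=float)[:, None]
        with pytest.warns(UserWarning):
            proxy = build_proxy_dataset(X, method="iqr")
            J, K, _ = optimize_jk(proxy, seed=0)
        assert (J, K) == (1, 1)

    def test_determinism(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        r1 = optimize_jk(proxy, seed=11)
        r2 = optimize_jk(proxy, seed=11)
        assert r1[:2] == r2[:2]
        np.testing.assert_array_equal(r1[2].score_matrix, r2[2].score_matrix)


class TestOptimizeTheta:
    def test_separable_recovery(self, blob_outliers):
        """Planted 10-sigma proxies: the chosen theta achieves G-means 1.0,
        i.e. it separates every fold-target ratio (below it) from every
        proxy ratio (at or above it)."""
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="kmor",
                                    kmor_config=KMORConfig(k=1, seed=0))
        scan = optimize_theta(proxy, inner_folds=2, seed=0)
        assert scan.theta_best in scan.candidates
        best_gm = scan.gmeans_by_candidate[
            list(scan.candidates).index(scan.theta_best)]
        assert best_gm == pytest.approx(1.0)
        # strict separation: exactly the 5 proxy-derived candidates sit at or
        # above the chosen threshold (smallest-theta tie rule picks the
        # boundary candidate itself)
        assert int(np.sum(scan.candidates >= scan.theta_best)) == \
            proxy.n_proxy_outliers

    def test_candidate_count_bounded_by_n(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        scan = optimize_theta(proxy, inner_folds=2, seed=0)
        assert len(scan.candidates) <= ds.n_samples
        assert len(scan.candidates) == len(scan.gmeans_by_candidate)

    def test_no_proxies_falls_back(self):
        X = np.arange(20, dtype=float)[:, None]
        with pytest.warns(UserWarning):
            proxy = build_proxy_dataset(X, method="iqr")
            scan = optimize_theta(proxy, seed=0, theta_fallback=1.5)
        assert scan.fallback_used and scan.theta_best == 1.5

    def test_determinism(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="iqr")
        s1 = optimize_theta(proxy, seed=5)
        s2 = optimize_theta(proxy, seed=5)
        assert s1.theta_best == s2.theta_best
        np.testing.assert_array_equal(s1.candidates, s2.candidates)


class TestOptimizeQ:
    def test_chosen_q_is_argmax_with_smallest_q_ties(self, blob_outliers):
        ds, _ = blob_outliers
        proxy = build_proxy_dataset(ds.features, method="kmor",
                                    kmor_config=KMORConfig(k=1, seed=0))
        q_best, scores = optimize_q(proxy, kmor_config=KMORConfig(k=1, seed=0),
                                    inner_folds=2, seed=0)
        usable = {q: s for q, s in scores.items() if not np.isnan(s)}
        top = max(usable.values())
        assert q_best == min(q for q, s in usable.items() if s == top)

    def test_no_proxies_falls_back_to_default(self):
        X = np.arange(20, dtype=float)[:, None]
        with pytest.warns(UserWarning):
            proxy = build_proxy_dataset(X, method="iqr")
            q_best, _ = optimize_q(proxy, seed=0)
        assert q_best == 0.9
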