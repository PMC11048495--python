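"""KMOR: objective arithmetic, exhaustive-enumeration recovery, Lloyd
equivalence at n0 = 0, monotone objective, cap enforcement, determinism."""
import numpy as np
import pytest

from oclab import ConfigError, DegenerateInputError, KMORConfig
from oclab.kmor import (OUTLIER_LABEL, kmor_fit, kmor_objective,
                        kmor_outliers, kmor_select_k)
from oclab.synthetic import generate, preset
from oracles import (enumerate_kmor_optimum as enumerate_optimal,
                     kmor_objective_oracle as objective_oracle,
                     lloyd_history as lloyd_oracle)


class TestObjective:
    def test_closed_form_one_cluster(self):
        X = np.array([[0.0], [1.0]])
        p = kmor_objective(X, np.array([0, 0]), np.array([[0.5]]), gamma=2.5)
        assert p == pytest.approx(0.5)

    def test_outlier_with_zero_average_distance(self):
        X = np.array([[0.0], [2.0]])
        p = kmor_objective(X, np.array([0, OUTLIER_LABEL]),
                           np.array([[0.0]]), gamma=2.5)
        assert p == 0.0  # D = gamma * 0 / 1 = 0, so the outlier term vanishes

    def test_all_outliers_degenerate(self):
        X = np.array([[0.0], [1.0]])
        with pytest.raises(DegenerateInputError):
            kmor_objective(X, np.array([OUTLIER_LABEL] * 2),
                           np.array([[0.0]]), gamma=1.0)

    def test_matches_independent_summation_oracle(self, rng):
        X = rng.normal(size=(20, 2))
        res = kmor_fit(X, KMORConfig(k=3, n0_fraction=0.1, seed=5))
        expected = objective_oracle(X, res.assignments, res.centers, 2.5)
        assert res.objective == pytest.approx(expected, rel=1e-12)


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_five_point_instance_recovers_global_optimum(self, seed):
        """{0,1,10,11,100}, k=2, n0=1: outlier {100}, centers {0.5, 10.5}."""
        X = np.array([[0.0], [1.0], [10.0], [11.0], [100.0]])
        res = kmor_fit(X, KMORConfig(k=2, gamma=2.5, n0_fraction=0.2, seed=seed))
        assert list(res.outlier_indices) == [4]
        assert sorted(res.centers.ravel()) == [0.5, 10.5]
        p_opt, assign_opt = enumerate_optimal(X, k=2, gamma=2.5, n0=1)
        assert res.objective == pytest.approx(p_opt)
        assert assign_opt[4] == OUTLIER_LABEL

    @pytest.mark.parametrize("trial", range(20))
    def test_lloyd_equivalence_with_no_outliers(self, trial):
        """n0=0 and shared init: per-iteration match with independent Lloyd."""
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(30, 2)) + rng.choice([0, 6], size=(30, 1))
        cfg = KMORConfig(k=2, n0_fraction=0.0, seed=trial, n_restarts=1)
        states = []
        res = kmor_fit(X, cfg, callback=lambda i, a, c: states.append((a, c)))
        init_centers = states[0][1]
        oracle = lloyd_oracle(X, init_centers, res.n_iterations)
        for (a_got, c_got), (a_exp, c_exp) in zip(states, oracle):
            np.testing.assert_array_equal(a_got, a_exp)
            np.testing.assert_allclose(c_got, c_exp, atol=1e-12)
        assert not np.any(res.assignments == OUTLIER_LABEL)

    @pytest.mark.parametrize("trial", range(25))
    def test_objective_monotone_and_cap_respected(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(20, 60))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        X[: n // 10] += 20  # some far points
        cfg = KMORConfig(k=int(rng.integers(1, 4)), n0_fraction=0.1,
                         seed=trial, n_restarts=1)
        res = kmor_fit(X, cfg)
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-12)
        assert len(res.outlier_indices) <= int(0.1 * n)
        # recomputing P from the returned state reproduces the last entry
        rec = kmor_objective(X, res.assignments, res.centers, cfg.gamma)
        assert rec == pytest.approx(res.objective, rel=1e-9)

    def test_rule1_consistency_after_convergence(self, rng):
        X = rng.normal(size=(80, 2))
        X[:4] += 15
        res = kmor_fit(X, KMORConfig(k=1, n0_fraction=0.1, seed=3))
        d2 = ((X - res.centers[0]) ** 2).sum(axis=1)
        out = res.assignments == OUTLIER_LABEL
        if not res.cap_hit:
            assert np.all(d2[~out] <= res.d_threshold_final + 1e-12)
            assert np.all(d2[out] > res.d_threshold_final)

    def test_n_equals_k_perfect_fit(self):
        X = np.array([[0.0], [5.0], [9.0]])
        res = kmor_fit(X, KMORConfig(k=3, n0_fraction=0.0, seed=0))
        assert res.objective == pytest.approx(0.0)
        assert len(res.outlier_indices) == 0

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ConfigError):
            kmor_fit(np.zeros((2, 1)), KMORConfig(k=3))

    def test_full_outlier_fraction_rejected(self):
        with pytest.raises(ConfigError):
            KMORConfig(k=1, n0_fraction=1.0)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(40, 3))
        cfg = KMORConfig(k=2, n0_fraction=0.05, seed=99)
        r1, r2 = kmor_fit(X, cfg), kmor_fit(X, cfg)
        np.testing.assert_array_equal(r1.assignments, r2.assignments)
        np.testing.assert_array_equal(r1.centers, r2.centers)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)


class TestSelectK:
    def test_reports_argmin_of_its_own_objectives(self, two_blobs):
        ds, _ = two_blobs
        k_best, results = kmor_select_k(ds.features, [1, 2, 3],
                                        KMORConfig(seed=1))
        objectives = {k: r.objective for k, r in results.items()}
        assert k_best == min(objectives, key=lambda k: (objectives[k], k))
        # the split from 1 to 2 clusters is enormous on separated blobs
        assert objectives[2] < 0.01 * objectives[1]

    def test_single_candidate(self, rng):
        X = rng.normal(size=(20, 2))
        k_best, results = kmor_select_k(X, [1], KMORConfig(seed=0))
        assert k_best == 1 and set(results) == {1}

    def test_duplicated_dataset_same_argmin(self, two_blobs):
        ds, _ = two_blobs
        X2 = np.vstack([ds.features, ds.features])
        k1, _ = kmor_select_k(ds.features, [1, 2], KMORConfig(seed=4))
        k2, _ = kmor_select_k(X2, [1, 2], KMORConfig(seed=4))
        assert k1 == k2


class TestOutlierDetection:
    def test_planted_outlier_flagged(self, rng):
        X = rng.normal(size=(200, 2))
        X[137] = [50.0, 50.0]
        idx = kmor_outliers(X, KMORConfig(k=1, n0_fraction=0.05, seed=0))
        assert 137 in idx

    def test_zero_cap_gives_empty_set(self, rng):
        X = rng.normal(size=(50, 2))
        assert len(kmor_outliers(X, KMORConfig(k=1, n0_fraction=0.0, seed=0))) == 0

    def test_cap_bounds_count_on_uniform_data(self, rng):
        X = rng.uniform(size=(200, 2))
        idx = kmor_outliers(X, KMORConfig(k=1, n0_fraction=0.05, seed=0))
        assert len(idx) <= 10
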