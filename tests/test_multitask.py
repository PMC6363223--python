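import numpy as np
import pytest

from multigrn import _solver
from multigrn.datasets import DataError, PriorMatrix
from multigrn.multitask import (PenaltyMatrix, SolverState, TaskData,
                                WeightDecomposition, build_penalty_matrix,
                                ebic, fit_gene, lambda_grid, objective,
                                precompute_covariances, select_model,
                                standardize_task, update_B, update_S)

from _oracles import penalized_objective, subgradient_minimize
from conftest import orthogonal_design


def _random_tasks(rng, p, d, n_range=(8, 20), k_true=2, noise=0.3):
    tasks = []
    w = rng.standard_normal(p) * (rng.permutation(p) < k_true)
    for j in range(d):
        n = int(rng.integers(*n_range))
        A = rng.standard_normal((p, n))
        x = A.T @ w + noise * rng.standard_normal(n)
        tasks.append(standardize_task(A, x, f"t{j}"))
    return tasks


class TestPenaltyMatrix:
    def test_rho_one_gives_all_ones(self):
        prior = PriorMatrix(["g1"], ["a", "b"], np.array([[1.0, 0.0]]))
        pm = build_penalty_matrix([prior], "g1", rho=1.0)
        np.testing.assert_array_equal(pm.values, np.ones((2, 1)))

    def test_four_tf_rescale_arithmetic(self):
        # one of four TFs in the prior, rho=2: column (1,1,1,1/2) * 4/3.5
        prior = PriorMatrix(["g1"], list("abcd"),
                            np.array([[0.0, 0.0, 0.0, 1.0]]))
        pm = build_penalty_matrix([prior], "g1", rho=2.0)
        expected = np.array([1.0, 1.0, 1.0, 0.5]) * (4 / 3.5)
        np.testing.assert_allclose(pm.values[:, 0], expected)
        assert pm.values[:, 0].sum() == pytest.approx(4.0)

    def test_per_dataset_priors_give_distinct_columns(self):
        p1 = PriorMatrix(["g1"], ["a", "b"], np.array([[1.0, 0.0]]))
        p2 = PriorMatrix(["g1"], ["a", "b"], np.array([[0.0, -1.0]]))
        pm = build_penalty_matrix([p1, p2], "g1", rho=3.0)
        assert pm.values[0, 0] < pm.values[1, 0]
        assert pm.values[1, 1] < pm.values[0, 1]

    def test_rho_below_one_rejected(self):
        prior = PriorMatrix(["g1"], ["a"], np.array([[1.0]]))
        with pytest.raises(DataError):
            build_penalty_matrix([prior], "g1", rho=0.5)


class TestCovarianceCache:
    def test_matches_direct_products(self, rng):
        tasks = _random_tasks(rng, p=4, d=3)
        state = precompute_covariances(tasks)
        for j, t in enumerate(tasks):
            np.testing.assert_allclose(state.gram[j], t.design @ t.design.T,
                                       atol=1e-10)
            np.testing.assert_allclose(state.atx[j], t.design @ t.response,
                                       atol=1e-10)
            assert state.xtx[j] == pytest.approx(t.response @ t.response)

    def test_orthogonal_design_gram_is_n_identity(self, rng):
        n = 16
        A = orthogonal_design(3, n, rng)
        state = precompute_covariances([TaskData("t", A, rng.standard_normal(n))])
        np.testing.assert_allclose(state.gram[0], n * np.eye(3), atol=1e-9)

    def test_single_sample_task_rejected(self):
        with pytest.raises(DataError):
            TaskData("t", np.ones((2, 1)), np.ones(1))


class TestCoordinateUpdates:
    def test_update_s_zeroes_below_threshold(self, rng):
        n = 20
        A = orthogonal_design(2, n, rng)
        x = 0.01 * A[0] / np.sqrt(n)      # weak signal
        state = precompute_covariances([TaskData("t", A, x)])
        S = update_S(state, np.zeros((2, 1)), np.zeros((2, 1)),
                     PenaltyMatrix(np.ones((2, 1))), lambda_s=1.0)
        assert (S == 0).all()

    def test_phi_zero_means_no_shrinkage(self, rng):
        n = 20
        A = orthogonal_design(2, n, rng)
        x = A.T @ np.array([0.7, 0.0])
        state = precompute_covariances([TaskData("t", A, x)])
        phi = PenaltyMatrix(np.array([[0.0], [1.0]]))
        S = update_S(state, np.zeros((2, 1)), np.zeros((2, 1)), phi,
                     lambda_s=5.0)
        # unpenalised coordinate equals its least-squares update
        assert S[0, 0] == pytest.approx(0.7, abs=1e-9)
        assert S[1, 0] == 0.0

    def test_update_s_closed_form_two_orthogonal_predictors(self, rng):
        n = 25
        A = orthogonal_design(2, n, rng)
        w_true = np.array([1.0, -0.5])
        x = A.T @ w_true
        state = precompute_covariances([TaskData("t", A, x)])
        lam = 0.2
        S = update_S(state, np.zeros((2, 1)), np.zeros((2, 1)),
                     PenaltyMatrix(np.ones((2, 1))), lam)
        alpha = A @ x / n
        expected = np.sign(alpha) * np.maximum(np.abs(alpha) - lam, 0)
        np.testing.assert_allclose(S[:, 0], expected, atol=1e-9)

    def test_update_b_single_dataset_is_scalar_soft_threshold(self, rng):
        n = 30
        A = orthogonal_design(3, n, rng)
        x = A.T @ np.array([0.9, 0.2, 0.0])
        state = precompute_covariances([TaskData("t", A, x)])
        lam = 0.3
        B = update_B(state, np.zeros((3, 1)), np.zeros((3, 1)), lam)
        S = update_S(state, np.zeros((3, 1)), np.zeros((3, 1)),
                     PenaltyMatrix(np.ones((3, 1))), lam)
        np.testing.assert_allclose(B, S, atol=1e-9)

    def test_linf_prox_row_zero_condition(self):
        # unit curvature, sum |v| <= lam_b: entire row collapses to zero
        v = np.array([0.2, -0.15])
        c = np.ones(2)
        out = np.empty(2)
        _solver._linf_prox_row(v, c, 0.4, out)
        np.testing.assert_array_equal(out, 0.0)

    def test_linf_prox_clips_to_shared_magnitude(self):
        # v=(0.9, 0.9), lam_b=0.4: both shrink to the common value 0.7
        v = np.array([0.9, 0.9])
        out = np.empty(2)
        _solver._linf_prox_row(v, np.ones(2), 0.4, out)
        np.testing.assert_allclose(out, [0.7, 0.7], atol=1e-12)

    def test_linf_prox_matches_numeric_minimizer(self, rng):
        """Row prox agrees with scipy minimisation of the 2-3 variable
        objective c/2 b^2 - v b + lam ||b||_inf."""
        from scipy.optimize import minimize
        for _ in range(10):
            d = int(rng.integers(1, 4))
            v = rng.standard_normal(d)
            c = rng.uniform(0.5, 2.0, d)
            lam = float(rng.uniform(0.05, 1.0))
            out = np.empty(d)
            _solver._linf_prox_row(v, c, lam, out)
            obj = lambda b: float(0.5 * (c * b * b).sum() - v @ b
                                  + lam * np.abs(b).max())
            res = min((minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000})
                       for x0 in (np.zeros(d), v / c, out)),
                      key=lambda r: r.fun)
            assert obj(out) <= res.fun + 1e-8


class TestFitGene:
    def test_full_shrinkage_gives_zero(self, rng):
        tasks = _random_tasks(rng, p=4, d=2)
        phi = PenaltyMatrix(np.ones((4, 2)))
        fit = fit_gene(tasks, phi, lambda_s=50.0, lambda_b=80.0)
        assert (fit.W == 0).all()

    def test_noise_free_shared_support_recovered(self, rng):
        p, d = 5, 3
        w = np.zeros(p)
        w[2] = 1.5
        tasks = []
        for j in range(d):
            A = rng.standard_normal((p, 30))
            tasks.append(standardize_task(A, A.T @ w, f"t{j}"))
        phi = PenaltyMatrix(np.ones((p, d)))
        fit = fit_gene(tasks, phi, lambda_s=0.02, lambda_b=0.03, tol=1e-10)
        assert set(map(tuple, np.argwhere(fit.W != 0))) == {(2, j) for j in range(d)}

    def test_objective_non_increasing_per_sweep(self, rng):
        tasks = _random_tasks(rng, p=5, d=3)
        state = precompute_covariances(tasks)
        phi = PenaltyMatrix(np.ones((5, 3)))
        lam_s, lam_b = 0.05, 0.08
        S = np.zeros((5, 3))
        B = np.zeros((5, 3))
        prev = np.inf
        for _ in range(15):
            _solver._sweep(state.gram, state.atx, state.nvec, phi.values,
                           lam_s, lam_b, True, np.ones(5, np.bool_), S, B)
            val = objective(state, phi, lam_s, lam_b, S, B)
            assert val <= prev + 1e-12
            prev = val

    def test_matches_subgradient_oracle(self, rng):
        """Objective at the solver's solution is never worse than a long
        plain-subgradient run on a 4-TF, 2-task instance."""
        tasks = _random_tasks(rng, p=4, d=2)
        state = precompute_covariances(tasks)
        phi = np.ones((4, 2))
        lam_s, lam_b = 0.08, 0.12
        fit = fit_gene(state, PenaltyMatrix(phi), lam_s, lam_b, tol=1e-10)
        ours = objective(state, PenaltyMatrix(phi), lam_s, lam_b, fit.S, fit.B)
        oracle = subgradient_minimize(state.gram, state.atx, state.xtx,
                                      state.nvec, phi, lam_s, lam_b, 100000)
        assert ours <= oracle + 1e-4 * max(1.0, abs(oracle))

    def test_cached_objective_matches_direct_evaluation(self, rng):
        tasks = _random_tasks(rng, p=4, d=2)
        state = precompute_covariances(tasks)
        phi = PenaltyMatrix(np.ones((4, 2)))
        fit = fit_gene(state, phi, 0.1, 0.15)
        via_cache = objective(state, phi, 0.1, 0.15, fit.S, fit.B)
        direct = penalized_objective(tasks, phi.values, 0.1, 0.15, fit.S, fit.B)
        assert via_cache == pytest.approx(direct, abs=1e-9)

    def test_identical_tasks_give_identical_columns(self, rng):
        p, n = 4, 25
        A = rng.standard_normal((p, n))
        x = A.T @ np.array([1.0, 0.0, -0.6, 0.0]) + 0.1 * rng.standard_normal(n)
        task = standardize_task(A, x)
        tasks = [TaskData(f"t{j}", task.design, task.response) for j in range(3)]
        fit = fit_gene(tasks, PenaltyMatrix(np.ones((p, 3))), 0.05, 0.08)
        for j in (1, 2):
            np.testing.assert_allclose(fit.W[:, j], fit.W[:, 0], atol=1e-9)

    def test_warm_start_reaches_same_solution(self, rng):
        tasks = _random_tasks(rng, p=4, d=2)
        phi = PenaltyMatrix(np.ones((4, 2)))
        cold = fit_gene(tasks, phi, 0.05, 0.08, tol=1e-12)
        coarse = fit_gene(tasks, phi, 0.5, 0.8, tol=1e-12)
        warm = fit_gene(tasks, phi, 0.05, 0.08, warm=coarse, tol=1e-12)
        np.testing.assert_allclose(warm.W, cold.W, atol=1e-6)

    def test_perfect_prior_never_loses_true_edges_on_orthogonal_design(self, rng):
        n, p = 36, 4
        A = orthogonal_design(p, n, rng)
        w = np.array([0.8, 0.0, 0.4, 0.0])
        x = A.T @ w + 0.05 * rng.standard_normal(n)
        task = TaskData("t", A, x)
        lam = 0.15
        base = fit_gene([task], PenaltyMatrix(np.ones((p, 1))), lam, 10 * lam)
        phi_vals = np.ones((p, 1))
        phi_vals[[0, 2], 0] = 0.0          # perfect prior confidence
        boosted = fit_gene([task], PenaltyMatrix(phi_vals), lam, 10 * lam)
        true_base = np.count_nonzero(base.W[[0, 2], 0])
        true_boost = np.count_nonzero(boosted.W[[0, 2], 0])
        assert true_boost >= true_base

    def test_zero_variance_predictor_pinned_to_zero(self, rng):
        p, n = 3, 20
        A = rng.standard_normal((p, n))
        A[1] = 5.0                          # constant predictor
        x = A.T @ np.array([1.0, 0.0, 0.0]) + 0.1 * rng.standard_normal(n)
        task = standardize_task(A, x)
        fit = fit_gene([task], PenaltyMatrix(np.ones((p, 1))), 0.05, 0.08)
        assert fit.W[1, 0] == 0.0

    def test_nonpositive_penalties_rejected(self, rng):
        tasks = _random_tasks(rng, p=3, d=1)
        with pytest.raises(DataError):
            fit_gene(tasks, PenaltyMatrix(np.ones((3, 1))), 0.0, 0.1)


class TestLambdaGrid:
    def test_ratio_contract(self, rng):
        tasks = _random_tasks(rng, p=6, d=2)
        grid = lambda_grid(tasks)
        for ls, lb in grid:
            assert 0.5 < ls / lb < 1.0

    def test_c_endpoints_map_to_grid_extremes(self, rng):
        tasks = _random_tasks(rng, p=6, d=2)
        import math
        p, d = 6, 2
        n_mean = np.mean([t.n for t in tasks])
        scale = math.sqrt(d * math.log(p) / n_mean)
        lbs = sorted({lb for _, lb in lambda_grid(tasks)})
        assert lbs[0] == pytest.approx(0.01 * scale)
        assert lbs[-1] == pytest.approx(10.0 * scale)

    def test_grid_size_and_determinism(self, rng):
        tasks = _random_tasks(rng, p=6, d=2)
        g1 = lambda_grid(tasks)
        g2 = lambda_grid(tasks)
        assert len(g1) == 20 * 5
        assert g1 == g2


class TestEbic:
    def _unit_state(self, n=10, p=3):
        # synthetic state: gram = I, atx chosen so RSS is easy to read off
        gram = np.eye(p)[None]
        atx = np.array([[0.5, 0.0, 0.0]])
        xtx = np.array([10.0])
        return SolverState(gram, atx, xtx, np.array([float(n)]), ["t"])

    def test_hand_case(self):
        """d=1, n=10, RSS=10, k=1, p=3, gamma=1 -> ln 10 + 2 ln 3."""
        state = self._unit_state()
        S = np.array([[1.0], [0.0], [0.0]])
        fit = WeightDecomposition(S, np.zeros((3, 1)), 0.1, 0.2)
        # RSS = xtx - 2*1*0.5 + 1 = 10
        val = ebic(fit, state, gamma=1.0)
        assert val == pytest.approx(np.log(10) + 2 * np.log(3))

    def test_gamma_zero_recovers_bic(self):
        state = self._unit_state()
        S = np.array([[1.0], [0.0], [0.0]])
        fit = WeightDecomposition(S, np.zeros((3, 1)), 0.1, 0.2)
        assert ebic(fit, state, gamma=0.0) == pytest.approx(np.log(10))

    def test_empty_model_value(self, rng):
        tasks = _random_tasks(rng, p=4, d=2)
        state = precompute_covariances(tasks)
        fit = WeightDecomposition(np.zeros((4, 2)), np.zeros((4, 2)), 1.0, 2.0)
        expected = np.mean([n * np.log(r / n) for n, r in
                            zip(state.nvec, state.xtx)])
        assert ebic(fit, state, gamma=1.0) == pytest.approx(expected)

    def test_gamma_out_of_range_rejected(self, rng):
        tasks = _random_tasks(rng, p=3, d=1)
        fit = WeightDecomposition(np.zeros((3, 1)), np.zeros((3, 1)), 1.0, 2.0)
        with pytest.raises(DataError):
            ebic(fit, tasks, gamma=1.5)

    def test_saturated_model_not_selectable(self):
        state = self._unit_state(n=3, p=3)
        S = np.ones((3, 1))
        fit = WeightDecomposition(S, np.zeros((3, 1)), 0.1, 0.2)
        assert ebic(fit, state, gamma=1.0) == np.inf


class TestSelectModel:
    def test_single_pair_grid_returns_that_fit(self, rng):
        tasks = _random_tasks(rng, p=4, d=2)
        phi = PenaltyMatrix(np.ones((4, 2)))
        sel = select_model(tasks, phi, [(0.1, 0.15)])
        direct = fit_gene(tasks, phi, 0.1, 0.15)
        np.testing.assert_allclose(sel.W, direct.W, atol=1e-9)

    def test_selected_ebic_is_grid_minimum(self, rng):
        """Exhaustive re-evaluation: every grid point refitted cold has
        EBIC >= the selected one."""
        tasks = _random_tasks(rng, p=4, d=2, n_range=(25, 30), noise=0.2)
        state = precompute_covariances(tasks)
        phi = PenaltyMatrix(np.ones((4, 2)))
        grid = lambda_grid(state)[::10]
        sel = select_model(state, phi, grid)
        for ls, lb in grid:
            cold = fit_gene(state, phi, ls, lb, tol=1e-10)
            assert ebic(cold, state) >= sel.ebic - 1e-6

    def test_planted_support_recovered_across_seeds(self):
        """n >> p: EBIC selection finds the planted sparse support in at
        least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p, d, n = 5, 2, 100
            w = np.zeros(p)
            w[[0, 3]] = [1.4, -1.1]
            tasks = []
            for j in range(d):
                A = rng.standard_normal((p, n))
                x = A.T @ w + 0.3 * rng.standard_normal(n)
                tasks.append(standardize_task(A, x, f"t{j}"))
            sel = select_model(tasks, PenaltyMatrix(np.ones((p, d))))
            if all(set(np.flatnonzero(sel.W[:, j])) == {0, 3} for j in range(d)):
                hits += 1
        assert hits >= 9

    def test_empty_grid_rejected(self, rng):
        tasks = _random_tasks(rng, p=3, d=1)
        with pytest.raises(DataError):
            select_model(tasks, PenaltyMatrix(np.ones((3, 1))), [])
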