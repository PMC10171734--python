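"""Both solvers: degenerate reductions, oracle equivalence, agreement, ADMM internals."""

import numpy as np
import pytest

from atmtl import (
    ADMMConfig,
    AGMConfig,
    MultiTaskDataset,
    PenaltyWeights,
    TemporalStructure,
    fit_admm,
    fit_agm,
    momentum_schedule,
    objective_value,
)
from atmtl.admm import ADMMState, residuals, update_auxiliary, update_duals, update_w_regression
from atmtl.objectives import lipschitz_bound
from conftest import random_dataset
from _oracles import full_objective_oracle, least_squares_per_task


class TestMomentumSchedule:
    def test_first_step_values(self):
        t1, a1 = momentum_schedule(1, 1.0)
        assert t1 == pytest.approx((1 + np.sqrt(5)) / 2)
        assert a1 == 0.0  # no momentum on the first step

    def test_sequence_grows_linearly(self):
        t_prev = 1.0
        for i in range(1, 50):
            t_prev, _ = momentum_schedule(i, t_prev)
        assert 20 < t_prev < 30  # t_k ~ k/2


class TestAGM:
    def test_unpenalized_matches_least_squares(self, rng):
        data, _ = random_dataset(rng, p=4, t=3, n_range=(20, 30))
        ts = TemporalStructure.create(0.3, 3)
        res = fit_agm(data, ts, PenaltyWeights(0, 0, 0, 0.3), AGMConfig(tol=1e-10, max_iter=20000))
        W_ls = least_squares_per_task(data)
        assert np.max(np.abs(res.W - W_ls)) < 1e-4

    def test_huge_l1_gives_exact_zero(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.0, 3)
        lam1 = 10 * max(np.max(np.abs(Xi.T @ yi)) for Xi, yi in zip(data.X, data.y))
        res = fit_agm(data, ts, PenaltyWeights(lam1, 0, 0, 0.0), AGMConfig())
        # subgradient condition: W=0 optimal iff lam1 >= |X^T y|_inf per task
        np.testing.assert_array_equal(res.W, 0.0)

    def test_matches_generic_convex_solver(self, rng):
        data, _ = random_dataset(rng, p=2, t=2, n_range=(4, 5))
        ts = TemporalStructure.create(0.3, 2)
        w = PenaltyWeights(0.1, 0.1, 0.1, 0.3)
        res = fit_agm(data, ts, w, AGMConfig(tol=1e-12, max_iter=50000))
        _, f_oracle = full_objective_oracle(data, ts, w)
        assert abs(res.objective - f_oracle) / abs(f_oracle) < 1e-4

    def test_trace_nonincreasing_with_line_search(self, rng):
        for seed_off in range(3):
            data, _ = random_dataset(np.random.default_rng(100 + seed_off), p=5, t=4)
            ts = TemporalStructure.create(0.2, 4)
            res = fit_agm(data, ts, PenaltyWeights(0.3, 0.2, 0.1, 0.2), AGMConfig(tol=1e-8))
            trace = np.array(res.objective_trace)
            assert np.all(np.diff(trace) <= 1e-10)

    def test_deterministic(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.25, 3)
        w = PenaltyWeights(0.2, 0.2, 0.2, 0.25)
        r1 = fit_agm(data, ts, w, AGMConfig())
        r2 = fit_agm(data, ts, w, AGMConfig())
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.W, r2.W)

    def test_fixed_step_from_lipschitz_bound_converges(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.3, 3)
        w = PenaltyWeights(0.2, 0.1, 0.1, 0.3)
        L = lipschitz_bound(data) * np.linalg.norm(ts.R_inv, 2) ** 2
        res = fit_agm(data, ts, w, AGMConfig(use_line_search=False, lipschitz_override=L, tol=1e-8))
        ref = fit_agm(data, ts, w, AGMConfig(tol=1e-10, max_iter=20000))
        assert res.converged
        assert abs(res.objective - ref.objective) / abs(ref.objective) < 1e-3

    def test_classification_converges_and_beats_zero(self, small_classification):
        data, W_true, _ = small_classification
        ts = TemporalStructure.create(0.2, data.t)
        w = PenaltyWeights(0.01, 0.01, 0.01, 0.2)
        res = fit_agm(data, ts, w, AGMConfig(tol=1e-8))
        assert res.converged
        zero_obj = objective_value(np.zeros_like(res.W), data, ts, w)
        assert res.objective < zero_obj

    def test_max_iter_exhaustion_reports_not_converged(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.3, 3)
        res = fit_agm(data, ts, PenaltyWeights(0.1, 0.1, 0.1, 0.3),
                      AGMConfig(max_iter=3, tol=1e-14))
        assert not res.converged
        assert res.n_iter == 3


class TestADMMInternals:
    @pytest.fixture
    def instance(self, rng):
        data, _ = random_dataset(rng, p=4, t=3, n_range=(15, 25))
        ts = TemporalStructure.create(0.3, 3)
        w = PenaltyWeights(0.2, 0.15, 0.1, 0.3)
        return data, ts, w

    def test_w_update_solves_its_linear_system(self, instance):
        data, ts, w = instance
        state = ADMMState.initialize(data, ts, rho=1.0)
        state.A = np.random.default_rng(0).normal(size=state.A.shape)
        W_new = update_w_regression(state, data, ts)
        # verify the linear-solve contract V_i w_i = q_i directly
        G = state.A @ ts.R.T
        for i in range(data.t):
            Vi = data.X[i].T @ data.X[i] + state.rho * (1 + state.M[i, i]) * np.eye(data.p)
            M_off = state.M.copy()
            np.fill_diagonal(M_off, 0.0)
            q = (data.X[i].T @ data.y[i] + state.rho * G[:, i]
                 - state.rho * (state.W @ M_off)[:, i] + state.rho * state.W[:, i])
            assert np.max(np.abs(Vi @ W_new[:, i] - q)) < 1e-9

    def test_w_update_fixed_point_minimizes_frozen_lagrangian(self, instance):
        data, ts, w = instance
        rng = np.random.default_rng(5)
        state = ADMMState.initialize(data, ts, rho=1.0)
        state.A = rng.normal(size=state.A.shape)
        state.B = rng.normal(size=state.B.shape)
        state.C = rng.normal(size=state.C.shape)
        state.D = rng.normal(size=state.D.shape)
        for _ in range(3000):  # iterate with A, B, duals frozen
            state.W = update_w_regression(state, data, ts)
        # exact minimizer of the W-block: solve the coupled linear system
        p, t = data.p, data.t
        Amat = np.zeros((p * t, p * t))
        rhs = np.zeros(p * t)
        for i in range(t):
            for j in range(t):
                block = state.rho * state.M[j, i] * np.eye(p)
                if i == j:
                    block = block + data.X[i].T @ data.X[i]
                Amat[i * p:(i + 1) * p, j * p:(j + 1) * p] = block
            rhs[i * p:(i + 1) * p] = (
                data.X[i].T @ data.y[i] - (state.C @ ts.R.T)[:, i]
                + state.rho * (state.A @ ts.R.T)[:, i]
                - (state.D @ ts.N.T)[:, i] + state.rho * (state.B @ ts.N.T)[:, i])
        W_exact = np.linalg.solve(Amat, rhs).reshape(t, p).T
        assert np.max(np.abs(state.W - W_exact)) < 1e-6

    def test_auxiliary_updates_reduce_to_identity_without_penalty(self, instance):
        data, ts, _ = instance
        rng = np.random.default_rng(1)
        state = ADMMState.initialize(data, ts, rho=2.0)
        state.W = rng.normal(size=state.W.shape)
        state.C = rng.normal(size=state.C.shape)
        state.D = rng.normal(size=state.D.shape)
        A, B = update_auxiliary(state, ts, PenaltyWeights(0, 0, 0, 0.3))
        np.testing.assert_allclose(A, state.W @ ts.R + state.C / 2.0, atol=1e-12)
        np.testing.assert_allclose(B, state.W @ ts.N + state.D / 2.0, atol=1e-12)

    def test_dual_update_unchanged_at_feasibility(self, instance):
        data, ts, _ = instance
        state = ADMMState.initialize(data, ts, rho=1.0)
        state.W = np.random.default_rng(2).normal(size=state.W.shape)
        state.A = state.W @ ts.R
        state.B = state.W @ ts.N
        C, D = update_duals(state, ts)
        np.testing.assert_allclose(C, state.C, atol=1e-14)
        np.testing.assert_allclose(D, state.D, atol=1e-14)

    def test_residuals_zero_at_feasible_unchanged_state(self, instance):
        data, ts, _ = instance
        state = ADMMState.initialize(data, ts, rho=1.0)
        state.W = np.random.default_rng(3).normal(size=state.W.shape)
        state.A = state.W @ ts.R
        state.B = state.W @ ts.N
        primal, dual = residuals(state, ts, state.A.copy(), state.B.copy())
        assert primal == pytest.approx(0.0, abs=1e-12)
        assert dual == pytest.approx(0.0, abs=1e-12)


class TestADMMFit:
    def test_unpenalized_matches_least_squares(self, rng):
        data, _ = random_dataset(rng, p=4, t=3, n_range=(20, 30))
        ts = TemporalStructure.create(0.3, 3)
        res = fit_admm(data, ts, PenaltyWeights(0, 0, 0, 0.3),
                       ADMMConfig(tol_primal=1e-7, tol_dual=1e-7, max_iter=20000))
        assert np.max(np.abs(res.W - least_squares_per_task(data))) < 1e-4

    def test_agreement_with_agm(self, rng):
        for _ in range(5):
            p, t = int(rng.integers(2, 6)), int(rng.integers(2, 5))
            data, _ = random_dataset(rng, p=p, t=t, n_range=(10, 30))
            alpha = rng.uniform(0, 0.5)
            ts = TemporalStructure.create(alpha, t)
            w = PenaltyWeights(*rng.uniform(0.01, 1, 3), alpha)
            r_admm = fit_admm(data, ts, w, ADMMConfig(tol_primal=1e-6, tol_dual=1e-6, max_iter=30000))
            r_agm = fit_agm(data, ts, w, AGMConfig(tol=1e-10, max_iter=30000))
            gap = abs(r_admm.objective - r_agm.objective) / abs(r_agm.objective)
            assert gap < 1e-3

    def test_residuals_decrease_to_zero_on_converging_run(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.2, 3)
        res = fit_admm(data, ts, PenaltyWeights(0.3, 0.2, 0.1, 0.2),
                       ADMMConfig(tol_primal=1e-6, tol_dual=1e-6, max_iter=20000))
        assert res.converged
        assert res.diagnostics["final_primal"] < 1e-6
        assert res.diagnostics["final_dual"] < 1e-6
        # feasibility gap driven well below coarse level
        assert res.diagnostics["primal_residuals"][-1] < 1e-3

    def test_rho_changes_speed_not_fixed_point(self, rng):
        data, _ = random_dataset(rng, p=4, t=3)
        ts = TemporalStructure.create(0.3, 3)
        w = PenaltyWeights(0.2, 0.2, 0.2, 0.3)
        objs, iters = [], []
        for rho in (0.5, 1.0, 5.0):
            r = fit_admm(data, ts, w, ADMMConfig(rho=rho, tol_primal=1e-6, tol_dual=1e-6,
                                                 max_iter=30000))
            objs.append(r.objective)
            iters.append(r.n_iter)
        ref = objs[1]
        assert all(abs(o - ref) / abs(ref) < 1e-3 for o in objs)
        assert len(set(iters)) > 1  # rho affects the path, not the solution

    def test_duals_bounded_on_converging_run(self, rng):
        data, _ = random_dataset(rng, p=3, t=3)
        ts = TemporalStructure.create(0.25, 3)
        res = fit_admm(data, ts, PenaltyWeights(0.5, 0.5, 0.5, 0.25),
                       ADMMConfig(tol_primal=1e-6, tol_dual=1e-6, max_iter=20000))
        assert res.converged

    def test_classification_agrees_with_agm(self, small_classification):
        data, _, _ = small_classification
        ts = TemporalStructure.create(0.2, data.t)
        w = PenaltyWeights(0.01, 0.01, 0.01, 0.2)
        r_admm = fit_admm(data, ts, w, ADMMConfig(tol_primal=1e-5, tol_dual=1e-5, max_iter=5000))
        r_agm = fit_agm(data, ts, w, AGMConfig(tol=1e-10, max_iter=30000))
        assert abs(r_admm.objective - r_agm.objective) / abs(r_agm.objective) < 1e-2
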