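"""Newton-coordinate-descent solver: subproblems, line search, full fits."""

import numpy as np
import pytest
import scipy.optimize

from perturbnet.model import SCGGMLayer, penalized_objective, scggm_gradients
from perturbnet.reference import reference_fit, reference_objective
from perturbnet.solver import (
    SolverOptions,
    compute_active_sets,
    fit_scggm,
    kkt_residual,
    line_search_lambda,
    newton_direction_lambda,
    update_theta,
)

from conftest import random_layer, random_stats


def theta_subproblem_oracle(Sxx, Sxy, Sigma, lam):
    """L-BFGS-B on the positive/negative split of the Θ Lasso subproblem."""
    p, q = Sxy.shape

    def fun(w):
        T = (w[: p * q] - w[p * q :]).reshape(p, q)
        g = 2.0 * np.sum(Sxy * T) + np.sum((T @ Sigma) * (Sxx @ T))
        grad = 2.0 * (Sxy + Sxx @ T @ Sigma)
        return g + lam * w.sum(), np.concatenate([(grad + lam).ravel(), (-grad + lam).ravel()])

    w0 = np.zeros(2 * p * q)
    res = scipy.optimize.minimize(
        fun, w0, jac=True, method="L-BFGS-B", bounds=[(0, None)] * (2 * p * q),
        options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return (res.x[: p * q] - res.x[p * q :]).reshape(p, q)


class TestUpdateTheta:
    def test_deadzone_keeps_theta_zero(self, rng):
        p, q = 3, 2
        Sxx, Sxy, Syy = random_stats(p, q, 30, rng)
        lam = 2.0 * np.abs(Sxy).max() + 1.0  # above the critical penalty
        layer = SCGGMLayer(Lambda=np.eye(q), Theta=np.zeros((p, q)), lambda_Theta=lam)
        gL, gT, Sigma, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        active = compute_active_sets(layer, gL, gT)
        update_theta(layer, Sxx, Sxy, Sigma, active)
        assert np.all(layer.Theta == 0.0)

    def test_scalar_stationarity(self):
        # p=q=1, Λ=1, Sxx=1, Sxy=-1, λ=0: 2 Sxy + 2 Λ^-1 Sxx Θ = 0 -> Θ=1
        layer = SCGGMLayer(Lambda=np.array([[1.0]]), Theta=np.array([[0.0]]))
        gL, gT, Sigma, _ = scggm_gradients(
            layer, np.array([[1.0]]), np.array([[-1.0]]), np.array([[1.0]])
        )
        active = compute_active_sets(layer, gL, gT)
        update_theta(layer, np.array([[1.0]]), np.array([[-1.0]]), Sigma, active)
        assert layer.Theta[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("lam", [0.05, 0.2])
    def test_matches_convex_oracle(self, rng, lam):
        p, q = 4, 3
        Sxx, Sxy, Syy = random_stats(p, q, 60, rng)
        layer = random_layer(p, q, rng, lam_T=lam)
        layer.Theta[:] = 0.0
        gL, gT, Sigma, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        for _ in range(400):  # enough sweeps to converge the subproblem
            active = compute_active_sets(layer, gL, gT)
            update_theta(layer, Sxx, Sxy, Sigma, active)
            gL, gT, _, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        oracle = theta_subproblem_oracle(Sxx, Sxy, Sigma, lam)
        assert np.abs(layer.Theta - oracle).max() < 1e-5

    def test_zero_variance_input_skipped_with_warning(self, rng):
        q = 2
        Sxx = np.diag([0.0, 1.0])
        Sxy = np.array([[0.5, 0.5], [0.2, 0.1]])
        layer = SCGGMLayer(Lambda=np.eye(q), Theta=np.zeros((2, q)), lambda_Theta=0.01)
        gL, gT, Sigma, _ = scggm_gradients(layer, Sxx, Sxy, np.eye(q))
        active = compute_active_sets(layer, gL, gT)
        with pytest.warns(UserWarning, match="zero variance"):
            update_theta(layer, Sxx, Sxy, Sigma, active)
        assert np.all(layer.Theta[0] == 0.0)


class TestNewtonDirection:
    def test_zero_at_unpenalized_stationary_point(self, rng):
        q = 4
        _, _, Syy = random_stats(2, q, 60, rng)
        layer = SCGGMLayer(
            Lambda=np.linalg.inv(Syy), Theta=np.zeros((0, q)), lambda_Lambda=0.0
        )
        gL, gT, Sigma, Psi = scggm_gradients(
            layer, np.zeros((0, 0)), np.zeros((0, q)), Syy
        )
        active = compute_active_sets(layer, gL, gT)
        D = newton_direction_lambda(layer, gL, Sigma, Psi, active)
        assert np.abs(D).max() < 1e-6

    def test_single_coordinate_matches_scalar_soft_threshold(self, rng):
        # one off-diagonal pair active: closed-form scalar update
        q = 3
        Sxx, Sxy, Syy = random_stats(2, q, 50, rng)
        layer = random_layer(2, q, rng, lam_L=0.15)
        gL, gT, Sigma, Psi = scggm_gradients(layer, Sxx, Sxy, Syy)
        i, j = 0, 2
        active = type(
            "A", (), {"set_Lambda": np.array([[i, j]]), "set_Theta": np.zeros((0, 2), int)}
        )()
        D = newton_direction_lambda(layer, gL, Sigma, Psi, active)
        Phi = Sigma + 2 * Psi
        a = Sigma[i, i] * Phi[j, j] + Sigma[j, j] * Phi[i, i] + 2 * Sigma[i, j] * Phi[i, j]
        b = 2 * gL[i, j]
        c = layer.Lambda[i, j]
        z = np.sign(c - b / a) * max(abs(c - b / a) - 2 * layer.lambda_Lambda / a, 0.0)
        assert D[i, j] == pytest.approx(z - c, rel=1e-12, abs=1e-12)
        assert D[j, i] == pytest.approx(D[i, j])

    def test_hessian_action_matches_finite_difference_of_gradient(self, rng):
        q = 3
        Sxx, Sxy, Syy = random_stats(3, q, 50, rng)
        layer = random_layer(3, q, rng)
        gL, _, Sigma, Psi = scggm_gradients(layer, Sxx, Sxy, Syy)
        Phi = Sigma + 2 * Psi
        D = rng.normal(size=(q, q))
        D = 0.5 * (D + D.T)
        # model Hessian action: Σ ⊗ Φ applied to vec(D) -> (Φ D Σ + Σ D Φ)/2 sym form
        action = 0.5 * (Phi @ D @ Sigma + Sigma @ D @ Phi)
        eps = 1e-6
        lp = SCGGMLayer(Lambda=layer.Lambda + eps * D, Theta=layer.Theta)
        lm = SCGGMLayer(Lambda=layer.Lambda - eps * D, Theta=layer.Theta)
        gp = scggm_gradients(lp, Sxx, Sxy, Syy)[0]
        gm = scggm_gradients(lm, Sxx, Sxy, Syy)[0]
        fd = (gp - gm) / (2 * eps)
        assert np.abs(fd - action).max() / max(1.0, np.abs(action).max()) < 1e-4


class TestLineSearch:
    def test_zero_direction_is_noop(self, rng):
        p, q = 2, 3
        Sxx, Sxy, Syy = random_stats(p, q, 30, rng)
        layer = random_layer(p, q, rng)
        gL = scggm_gradients(layer, Sxx, Sxy, Syy)[0]
        f0 = penalized_objective(layer, Sxx, Sxy, Syy)
        Lam0 = layer.Lambda.copy()
        alpha, f1 = line_search_lambda(
            layer, Sxx, Sxy, Syy, np.zeros((q, q)), gL, SolverOptions()
        )
        assert alpha == 0.0 and f1 == pytest.approx(f0)
        assert np.array_equal(layer.Lambda, Lam0)

    def test_descent_on_newton_direction(self, rng):
        p, q = 3, 4
        Sxx, Sxy, Syy = random_stats(p, q, 60, rng)
        layer = random_layer(p, q, rng)
        gL, gT, Sigma, Psi = scggm_gradients(layer, Sxx, Sxy, Syy)
        active = compute_active_sets(layer, gL, gT)
        D = newton_direction_lambda(layer, gL, Sigma, Psi, active)
        assert np.any(D)
        f0 = penalized_objective(layer, Sxx, Sxy, Syy)
        _, f1 = line_search_lambda(layer, Sxx, Sxy, Syy, D, gL, SolverOptions())
        assert f1 < f0


class TestActiveSets:
    def test_huge_penalty_leaves_only_diagonal(self, rng):
        q = 4
        Sxx, Sxy, Syy = random_stats(3, q, 30, rng)
        layer = SCGGMLayer(
            Lambda=np.eye(q), Theta=np.zeros((3, q)), lambda_Lambda=1e6, lambda_Theta=1e6
        )
        gL, gT, _, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        act = compute_active_sets(layer, gL, gT)
        assert act.m_Theta == 0
        assert act.m_Lambda == q
        assert np.all(act.set_Lambda[:, 0] == act.set_Lambda[:, 1])

    def test_matches_brute_force_rule(self, rng):
        p, q = 4, 5
        Sxx, Sxy, Syy = random_stats(p, q, 40, rng)
        layer = random_layer(p, q, rng, lam_L=0.3, lam_T=0.3)
        gL, gT, _, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        act = compute_active_sets(layer, gL, gT)
        got_L = {(int(i), int(j)) for i, j in act.set_Lambda}
        expect_L = set()
        for i in range(q):
            expect_L.add((i, i))
            for j in range(i + 1, q):
                if abs(gL[i, j]) > 0.3 or layer.Lambda[i, j] != 0:
                    expect_L.add((i, j))
        assert got_L == expect_L
        got_T = {(int(i), int(j)) for i, j in act.set_Theta}
        expect_T = {
            (i, j)
            for i in range(p)
            for j in range(q)
            if abs(gT[i, j]) > 0.3 or layer.Theta[i, j] != 0
        }
        assert got_T == expect_T

    def test_nonzero_entries_always_active(self, rng):
        p, q = 3, 3
        Sxx, Sxy, Syy = random_stats(p, q, 30, rng)
        layer = random_layer(p, q, rng, lam_L=1e5, lam_T=1e5)
        gL, gT, _, _ = scggm_gradients(layer, Sxx, Sxy, Syy)
        act = compute_active_sets(layer, gL, gT)
        nz = set(zip(*np.nonzero(layer.Theta)))
        assert nz <= {(int(i), int(j)) for i, j in act.set_Theta}


class TestFitScggm:
    def test_infinite_penalty_limit(self, rng):
        p, q = 3, 4
        Sxx, Sxy, Syy = random_stats(p, q, 50, rng)
        layer, _ = fit_scggm(Sxx, Sxy, Syy, 1e6, 1e6)
        assert np.all(layer.Theta == 0.0)
        off = layer.Lambda - np.diag(np.diag(layer.Lambda))
        assert np.all(off == 0.0)
        assert np.allclose(np.diag(layer.Lambda), 1.0 / np.diag(Syy), rtol=1e-5)

    def test_unpenalized_matches_conditional_mle(self, rng):
        p, q, n = 3, 2, 4000
        X = rng.normal(size=(n, p))
        B = rng.normal(size=(p, q)) * 0.5
        Y = X @ B + rng.normal(size=(n, q))
        Sxx, Sxy = X.T @ X / n, X.T @ Y / n
        Sxx -= np.outer(X.mean(0), X.mean(0))
        Sxy -= np.outer(X.mean(0), Y.mean(0))
        Yc = Y - Y.mean(0)
        Syy = Yc.T @ Yc / n
        Xc = X - X.mean(0)
        Sxx = Xc.T @ Xc / n
        Sxy = Xc.T @ Yc / n
        layer, _ = fit_scggm(
            Sxx, Sxy, Syy, 0.0, 0.0, options=SolverOptions(tol=1e-10, max_iter=300)
        )
        Lam_mle = np.linalg.inv(Syy - Sxy.T @ np.linalg.solve(Sxx, Sxy))
        Theta_mle = -np.linalg.solve(Sxx, Sxy) @ Lam_mle
        assert np.allclose(layer.Lambda, Lam_mle, rtol=1e-3, atol=1e-3)
        assert np.allclose(layer.Theta, Theta_mle, rtol=1e-3, atol=1e-3)

    def test_objective_matches_reference_solver(self, rng):
        p, q, n = 6, 4, 60
        Sxx, Sxy, Syy = random_stats(p, q, n, rng)
        for lam in (0.05, 0.2):
            layer, _ = fit_scggm(
                Sxx, Sxy, Syy, lam, lam, options=SolverOptions(tol=1e-9, max_iter=200)
            )
            ours = penalized_objective(layer, Sxx, Sxy, Syy)
            ref = reference_fit(Sxx, Sxy, Syy, lam, lam)
            ref_obj = reference_objective(ref, Sxx, Sxy, Syy)
            assert abs(ours - ref_obj) <= 1e-6 * abs(ref_obj)

    def test_monotone_trajectory_and_kkt(self, rng):
        p, q = 5, 4
        Sxx, Sxy, Syy = random_stats(p, q, 80, rng)
        layer, state = fit_scggm(
            Sxx, Sxy, Syy, 0.1, 0.1, options=SolverOptions(tol=1e-9, max_iter=200)
        )
        traj = np.array(state.objective_trajectory)
        assert np.all(np.diff(traj) <= 1e-12)
        assert kkt_residual(layer, Sxx, Sxy, Syy) < 1e-3

    def test_sample_permutation_invariance(self, rng):
        from perturbnet.model import DataBundle, compute_suffstats

        p, q, n = 4, 3, 50
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, q))
        Z = np.zeros((n, 1))
        perm = rng.permutation(n)
        s1 = compute_suffstats(DataBundle(X=X, Y=Y, Z=Z))
        s2 = compute_suffstats(DataBundle(X=X[perm], Y=Y[perm], Z=Z[perm]))
        l1, _ = fit_scggm(s1.S_xx, s1.S_xy, s1.S_yy, 0.1, 0.1)
        l2, _ = fit_scggm(s2.S_xx, s2.S_xy, s2.S_yy, 0.1, 0.1)
        assert np.abs(l1.Lambda - l2.Lambda).max() < 1e-6
        assert np.abs(l1.Theta - l2.Theta).max() < 1e-6

    def test_graphical_lasso_special_case(self, rng):
        from sklearn.covariance import graphical_lasso

        q, n = 5, 200
        _, _, Syy = random_stats(2, q, n, rng)
        lam = 0.1
        layer, _ = fit_scggm(
            np.zeros((0, 0)),
            np.zeros((0, q)),
            Syy,
            lam,
            lam,
            options=SolverOptions(tol=1e-10, max_iter=300),
        )
        _, prec = graphical_lasso(Syy, alpha=lam, tol=1e-10, max_iter=500)
        assert np.abs(layer.Lambda - prec).max() < 1e-3
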