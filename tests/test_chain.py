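"""Chain estimation: decoupling, BIC, grid selection, EM, CG posterior."""

import numpy as np
import pytest

from perturbnet.chain import (
    ChainLambdas,
    RegularizationGrid,
    bic_score,
    em_fit,
    fit_chain,
    implicit_posterior_solve,
    select_lambdas,
)
from perturbnet.model import (
    DataBundle,
    SCGGMLayer,
    ChainModel,
    compute_suffstats,
    penalized_objective,
)
from perturbnet.simulate import SimConfig, make_ground_truth, sample_dataset
from perturbnet.solver import SolverOptions, fit_scggm

LAM = ChainLambdas(0.1, 0.1, 0.1, 0.1)


@pytest.fixture(scope="module")
def sim_data():
    cfg = SimConfig(p=30, q=20, r=6, module_size=10, n_snps_perturbing=15, seed=3)
    truth = make_ground_truth(cfg, seed=3)
    data = sample_dataset(truth, n=150, seed=5)
    return truth, data


class TestFitChain:
    def test_objective_is_sum_of_independent_layer_minima(self, sim_data):
        _, data = sim_data
        stats = compute_suffstats(data)
        model = fit_chain(data, LAM, stats=stats)
        lxy, _ = fit_scggm(*stats.layer_xy(), 0.1, 0.1)
        lyz, _ = fit_scggm(*stats.layer_yz(), 0.1, 0.1)
        expect = penalized_objective(lxy, *stats.layer_xy()) + penalized_objective(
            lyz, *stats.layer_yz()
        )
        assert model.fit_info["objective"] == pytest.approx(expect)

    def test_recovers_truth_better_than_null(self, sim_data):
        from perturbnet.evaluate import support_auc

        truth, data = sim_data
        model = fit_chain(data, LAM)
        iu = np.triu_indices(truth.model.q, k=1)
        auc = support_auc(model.layer_xy.Lambda[iu], truth.mask_network_y[iu])
        assert auc > 0.6  # clearly above a random (0.5) scorer

    def test_gene_permutation_equivariance(self, sim_data):
        _, data = sim_data
        perm = np.random.default_rng(0).permutation(data.q)
        data_p = DataBundle(
            X=data.X,
            Y=data.Y[:, perm],
            Z=data.Z,
            gene_ids=[data.gene_ids[i] for i in perm],
            snp_ids=data.snp_ids,
            trait_ids=data.trait_ids,
        )
        # coordinate visitation order differs under permutation, so agreement
        # is limited by solver tolerance; tighten it and compare loosely
        opts = SolverOptions(tol=1e-12, max_iter=1000)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = fit_chain(data, LAM, options=opts)
            m2 = fit_chain(data_p, LAM, options=opts)
        assert np.abs(m1.layer_xy.Lambda[np.ix_(perm, perm)] - m2.layer_xy.Lambda).max() < 1e-4
        assert np.abs(m1.layer_xy.Theta[:, perm] - m2.layer_xy.Theta).max() < 1e-4
        assert np.abs(m1.layer_yz.Theta[perm, :] - m2.layer_yz.Theta).max() < 1e-4


class TestBIC:
    def test_parameter_count_rule(self):
        Lam = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, 0.0], [0.0, 0.0, 1.0]])
        Th = np.zeros((4, 3))
        Th[0, 0] = Th[2, 1] = 0.5
        layer = SCGGMLayer(Lambda=Lam, Theta=Th)
        from perturbnet.chain import _param_count

        assert _param_count(layer) == 2 + 1 + 3

    def test_sparser_wins_at_equal_likelihood(self):
        # same Λ/Θ values -> same likelihood; extra nonzero -> lower score
        q = 3
        Syy = np.eye(q)
        dense = SCGGMLayer(Lambda=np.eye(q) + 0.0, Theta=np.zeros((2, q)))
        denser = SCGGMLayer(Lambda=np.eye(q), Theta=np.zeros((2, q)))
        denser.Theta[0, 0] = 1e-300  # structurally nonzero, numerically nil
        s1 = bic_score(dense, (np.eye(2), np.zeros((2, q)), Syy), n=50)
        s2 = bic_score(denser, (np.eye(2), np.zeros((2, q)), Syy), n=50)
        assert s1 > s2

    def test_mild_penalty_beats_saturated_on_dependent_data(self, rng):
        q, n = 6, 300
        A = rng.normal(size=(q, q)) * 0.4
        cov = A @ A.T + np.eye(q)
        Y = rng.multivariate_normal(np.zeros(q), cov, size=n)
        Yc = Y - Y.mean(0)
        Syy = Yc.T @ Yc / n
        sl = (np.zeros((0, 0)), np.zeros((0, q)), Syy)
        mild, _ = fit_scggm(*sl, 0.05, 0.05)
        sat, _ = fit_scggm(*sl, 1e6, 1e6)
        assert bic_score(mild, sl, n) > bic_score(sat, sl, n)


class TestSelectLambdas:
    def test_single_candidate_equals_fit_chain(self, sim_data):
        _, data = sim_data
        grid = RegularizationGrid(
            lambda_Lambda_y=(0.1,),
            lambda_Theta_xy=(0.1,),
            lambda_Lambda_z=(0.1,),
            lambda_Theta_yz=(0.1,),
        )
        m_grid, tables = select_lambdas(data, grid)
        m_fit = fit_chain(data, LAM)
        assert np.allclose(m_grid.layer_xy.Lambda, m_fit.layer_xy.Lambda)
        assert np.allclose(m_grid.layer_yz.Theta, m_fit.layer_yz.Theta)
        assert len(tables["xy"]) == 1 and len(tables["yz"]) == 1

    def test_score_table_size_is_grid_product(self, sim_data):
        _, data = sim_data
        grid = RegularizationGrid(
            lambda_Lambda_y=(0.3, 0.1),
            lambda_Theta_xy=(0.3, 0.1, 0.05),
            lambda_Lambda_z=(0.2,),
            lambda_Theta_yz=(0.2, 0.1),
        )
        _, tables = select_lambdas(data, grid)
        assert len(tables["xy"]) == 2 * 3
        assert len(tables["yz"]) == 1 * 2

    def test_selected_support_beats_grid_extremes(self):
        cfg = SimConfig(p=20, q=15, r=4, module_size=5, n_snps_perturbing=10, seed=9)
        truth = make_ground_truth(cfg, seed=9)
        data = sample_dataset(truth, n=250, seed=10)
        grid = RegularizationGrid(
            lambda_Lambda_y=(2.0, 0.15, 0.01),
            lambda_Theta_xy=(2.0, 0.15, 0.01),
            lambda_Lambda_z=(0.15,),
            lambda_Theta_yz=(0.15,),
        )
        model, _ = select_lambdas(data, grid)

        def f1_support(est, true):
            est, true = est != 0, true
            tp = (est & true).sum()
            prec = tp / max(est.sum(), 1)
            rec = tp / max(true.sum(), 1)
            return 2 * prec * rec / max(prec + rec, 1e-12)

        iu = np.triu_indices(truth.model.q, k=1)
        sel = f1_support(model.layer_xy.Lambda[iu], truth.mask_network_y[iu])
        for lam in (2.0, 0.01):
            ext = fit_chain(data, ChainLambdas(lam, lam, 0.15, 0.15))
            f_ext = f1_support(ext.layer_xy.Lambda[iu], truth.mask_network_y[iu])
            assert sel >= f_ext - 1e-12


class TestEM:
    def test_no_hidden_rows_reduces_to_fit_chain(self, sim_data):
        _, data = sim_data
        m1 = fit_chain(data, LAM)
        m2, state = em_fit(data, LAM)
        assert state.iterations == 0
        assert np.array_equal(m1.layer_xy.Lambda, m2.layer_xy.Lambda)
        assert np.array_equal(m1.layer_yz.Theta, m2.layer_yz.Theta)

    def test_posterior_toy_hand_inversion(self):
        # Λ_y = I2, Θ_yz = [[1],[0]], Λ_z = [2], Θ_xy = 0, z = 1:
        # Σ = [[1.5, 0], [0, 1]]^-1, μ = -Σ (Θ_yz z) = (-2/3, 0)
        from perturbnet.chain import _posterior

        layer_xy = SCGGMLayer(Lambda=np.eye(2), Theta=np.zeros((1, 2)))
        layer_yz = SCGGMLayer(
            Lambda=np.array([[2.0]]),
            Theta=np.array([[1.0], [0.0]]),
            input_ids=layer_xy.output_ids,
        )
        model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
        mu, Sig = _posterior(model, np.zeros((1, 1)), np.ones((1, 1)))
        assert np.allclose(Sig, np.array([[2 / 3, 0.0], [0.0, 1.0]]))
        assert np.allclose(mu, np.array([[-2 / 3, 0.0]]))
        # cross-check by conditioning the joint Gaussian numerically
        from perturbnet.inference import build_joint

        J = build_joint(model)
        Cov = np.linalg.inv(J.Lambda_zy)  # over (z, y)
        Czz, Czy = Cov[:1, :1], Cov[:1, 1:]
        Cyy = Cov[1:, 1:]
        Sig_cond = Cyy - Czy.T @ np.linalg.solve(Czz, Czy)
        mu_cond = Czy.T @ np.linalg.solve(Czz, np.ones((1, 1)))
        assert np.allclose(Sig, Sig_cond, atol=1e-8)
        assert np.allclose(mu.ravel(), mu_cond.ravel(), atol=1e-8)

    def test_zero_coupling_posterior_is_lambda_y(self, sim_data):
        from perturbnet.chain import _posterior

        _, data = sim_data
        model = fit_chain(data, LAM)
        model.layer_yz.Theta[:] = 0.0
        x = data.X[:2] - data.X.mean(0)
        z = data.Z[:2] - data.Z.mean(0)
        mu, Sig = _posterior(model, x, z)
        assert np.allclose(
            np.linalg.inv(Sig), model.layer_xy.Lambda, atol=1e-8
        )
        mu_expected = -(x @ model.layer_xy.Theta) @ Sig
        assert np.allclose(mu, mu_expected)

    def test_em_monotone_and_consistent_with_complete_fit(self, sim_data):
        _, data = sim_data
        rng = np.random.default_rng(2)

        def support_overlap(m):
            ref = fit_chain(data, LAM)
            a = m.layer_xy.Lambda != 0
            b = ref.layer_xy.Lambda != 0
            return (a & b).sum() / max(b.sum(), 1)

        overlaps = []
        for frac in (0.1, 0.5):
            obs = np.ones(data.n, bool)
            obs[rng.choice(data.n, size=int(frac * data.n), replace=False)] = False
            d = DataBundle(X=data.X, Y=data.Y, Z=data.Z, observed=obs)
            model, state = em_fit(d, LAM, max_em_iter=10)
            traj = np.array(state.observed_objective)
            assert np.all(np.diff(traj) <= 1e-8 * np.maximum(1.0, np.abs(traj[:-1])))
            overlaps.append(support_overlap(model))
        assert overlaps[0] >= overlaps[1] - 0.15  # mild hiding hurts less

    def test_traits_inform_imputation(self):
        # strong y->z coupling: posterior mean must beat the x-only predictor
        cfg = SimConfig(p=10, q=8, r=8, module_size=4, n_snps_perturbing=8, seed=21)
        truth = make_ground_truth(cfg, seed=21)
        data = sample_dataset(truth, n=400, seed=22)
        obs = np.ones(400, bool)
        obs[300:] = False
        d = DataBundle(X=data.X, Y=data.Y, Z=data.Z, observed=obs)
        model, state = em_fit(d, ChainLambdas(0.05, 0.05, 0.05, 0.05), max_em_iter=10)
        hidden_true = data.Y[300:] - data.Y[:300].mean(0)
        mu = state.posterior_mean
        from perturbnet.inference import indirect_xy

        B = indirect_xy(model.layer_xy)
        x_only = (data.X[300:] - data.X.mean(0)) @ B
        c_post = np.corrcoef(mu.ravel(), hidden_true.ravel())[0, 1]
        c_xonly = np.corrcoef(x_only.ravel(), hidden_true.ravel())[0, 1]
        assert c_post > c_xonly + 0.1


class TestImplicitPosterior:
    def test_zero_coupling_gives_lambda_y_inverse_column(self, small_chain):
        small_chain.layer_yz.Theta[:] = 0.0
        col = implicit_posterior_solve(small_chain, 1)
        expect = np.linalg.inv(small_chain.layer_xy.Lambda)[:, 1]
        assert np.abs(col - expect).max() < 1e-6

    def test_matches_dense_inverse_q30(self, rng):
        from conftest import random_spd

        q, r = 30, 4
        layer_xy = SCGGMLayer(Lambda=random_spd(q, rng), Theta=np.zeros((2, q)))
        Th_yz = rng.normal(size=(q, r)) * (rng.random((q, r)) < 0.2)
        layer_yz = SCGGMLayer(
            Lambda=random_spd(r, rng), Theta=Th_yz, input_ids=layer_xy.output_ids
        )
        model = ChainModel(layer_xy=layer_xy, layer_yz=layer_yz)
        P = layer_xy.Lambda + Th_yz @ np.linalg.solve(layer_yz.Lambda, Th_yz.T)
        dense = np.linalg.inv(P)
        for col in (0, 7, 29):
            v = implicit_posterior_solve(model, col)
            assert np.abs(v - dense[:, col]).max() < 1e-6
            e = np.zeros(q)
            e[col] = 1.0
            assert np.linalg.norm(P @ v - e) < 1e-7
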