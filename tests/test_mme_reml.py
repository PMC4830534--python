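import numpy as np
import pytest
from scipy.optimize import minimize

import hybridgblup as hg
from hybridgblup.mme_reml import (
    ModelSpec,
    VarianceComponents,
    _Workspace,
    build_mme,
    dense_design,
    em_update_genetic,
    em_update_residual,
    fit_gblup,
    solve_mme,
)


def _random_pd(n, rng, jitter=0.5):
    M = rng.standard_normal((n, n + 3))
    return M @ M.T / (n + 3) + jitter * np.eye(n)


class TestModelSpec:
    def test_variant_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("GBLUP", ["a"])
        with pytest.raises(ValueError):
            ModelSpec("MV-A", ["a"])
        assert ModelSpec("UV-AD", ["a"]).include_dominance
        assert not ModelSpec("MV-A", ["a", "b"]).include_dominance


class TestBuildSolve:
    def test_identity_kinship_unit_variances_pattern(self):
        """UV additive model, n=3, A=I, all variances 1: the coefficient
        matrix is [[n, 1'], [1, 2I]] for (mu, alpha)."""
        n = 3
        y = np.array([1.0, 2.0, 3.0])
        vc = VarianceComponents(V_alpha=[[1.0]], R=[[1.0]])
        C, rhs = build_mme(y.reshape(-1, 1), vc, np.eye(n))
        expected = np.block(
            [[np.array([[n]]), np.ones((1, n))], [np.ones((n, 1)), 2 * np.eye(n)]]
        )
        np.testing.assert_allclose(C, expected)
        np.testing.assert_allclose(rhs, np.concatenate([[y.sum()], y]))
        # solution matches a ridge regression on centered identity features
        beta, alpha, _, _ = solve_mme(C, rhs, n, 1, False)
        resid = y - beta[0] - alpha[0]
        np.testing.assert_allclose(resid, alpha[0])  # lambda = 1 shrinkage

    def test_diagonal_covariances_decouple_to_univariate(self):
        """With diagonal V_alpha and R the multivariate MME solution equals
        the per-trait univariate solutions."""
        rng = np.random.default_rng(4)
        n, t = 8, 2
        A = _random_pd(n, rng)
        Y = rng.standard_normal((n, t))
        Va = np.diag([1.5, 0.7])
        R = np.diag([1.0, 2.0])
        C, rhs = build_mme(Y, VarianceComponents(V_alpha=Va, R=R), np.linalg.inv(A))
        beta, alpha, _, _ = solve_mme(C, rhs, n, t, False)
        for ti in range(t):
            vc1 = VarianceComponents(V_alpha=[[Va[ti, ti]]], R=[[R[ti, ti]]])
            C1, rhs1 = build_mme(Y[:, ti : ti + 1], vc1, np.linalg.inv(A))
            b1, a1, _, _ = solve_mme(C1, rhs1, n, 1, False)
            assert beta[ti] == pytest.approx(b1[0], abs=1e-10)
            np.testing.assert_allclose(alpha[ti], a1[0], atol=1e-10)

    def test_no_dominance_block_for_additive_variant(self):
        n = 4
        y = np.zeros((n, 1))
        vc = VarianceComponents(V_alpha=[[1.0]], R=[[1.0]])
        C, _ = build_mme(y, vc, np.eye(n))
        assert C.shape == (1 + n, 1 + n)

    def test_shrinkage_limit_constant_data(self):
        """Huge residual-to-genetic variance ratio: beta -> mean, BLUPs -> 0."""
        n = 5
        y = np.full((n, 1), 3.7)
        vc = VarianceComponents(V_alpha=[[1e-8]], R=[[1.0]])
        C, rhs = build_mme(y, vc, np.eye(n))
        beta, alpha, _, _ = solve_mme(C, rhs, n, 1, False)
        assert beta[0] == pytest.approx(3.7, abs=1e-6)
        np.testing.assert_allclose(alpha, 0.0, atol=1e-6)

    def test_mme_solution_maximizes_joint_density(self):
        """On a 5-individual, 2-trait dominance instance the MME solution
        equals the joint-density maximizer found by two independent
        routes: penalized least squares (QR) and a quasi-Newton optimizer."""
        rng = np.random.default_rng(11)
        n, t = 5, 2
        A = _random_pd(n, rng)
        D = _random_pd(n, rng)
        Y = rng.standard_normal((n, t))
        Va = np.array([[1.0, 0.3], [0.3, 0.8]])
        Vd = np.array([[0.6, 0.1], [0.1, 0.9]])
        R = np.array([[1.0, -0.2], [-0.2, 1.5]])
        vc = VarianceComponents(V_alpha=Va, R=R, V_delta=Vd)
        C, rhs = build_mme(Y, vc, np.linalg.inv(A), np.linalg.inv(D))
        beta, alpha, delta, _ = solve_mme(C, rhs, n, t, True)
        mme_sol = np.concatenate([beta, alpha.ravel(), delta.ravel()])

        y_st, W, _, _ = dense_design(Y, True)
        R_inv = np.linalg.inv(np.kron(R, np.eye(n)))
        Ga_inv = np.linalg.inv(np.kron(Va, A))
        Gd_inv = np.linalg.inv(np.kron(Vd, D))
        dim = W.shape[1]
        sl_a = slice(t, t + n * t)
        sl_d = slice(t + n * t, dim)

        # route 1: stacked penalized least squares solved by QR
        Lr = np.linalg.cholesky(R_inv)
        La = np.linalg.cholesky(Ga_inv)
        Ld = np.linalg.cholesky(Gd_inv)
        Pa = np.zeros((n * t, dim))
        Pa[:, sl_a] = La.T
        Pd = np.zeros((n * t, dim))
        Pd[:, sl_d] = Ld.T
        stacked = np.vstack([Lr.T @ W, Pa, Pd])
        target = np.concatenate([Lr.T @ y_st, np.zeros(2 * n * t)])
        sol_qr, *_ = np.linalg.lstsq(stacked, target, rcond=None)
        np.testing.assert_allclose(sol_qr, mme_sol, atol=1e-8)

        # route 2: generic optimizer on the joint negative log-density
        def neg_logdens(theta):
            r = y_st - W @ theta
            pen = theta[sl_a] @ Ga_inv @ theta[sl_a] + theta[sl_d] @ Gd_inv @ theta[sl_d]
            return 0.5 * (r @ R_inv @ r + pen)

        def grad(theta):
            r = y_st - W @ theta
            g = -W.T @ (R_inv @ r)
            g[sl_a] += Ga_inv @ theta[sl_a]
            g[sl_d] += Gd_inv @ theta[sl_d]
            return g

        opt = minimize(neg_logdens, np.zeros(dim), jac=grad, method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(opt.x, mme_sol, atol=1e-6)

    def test_singular_variance_matrix_advises_restart(self):
        n = 3
        vc = VarianceComponents(V_alpha=[[0.0]], R=[[1.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            build_mme(np.zeros((n, 1)), vc, np.eye(n))


class TestEMUpdates:
    def test_genetic_update_plug_in(self):
        u = np.array([1.0, 1.0])
        assert em_update_genetic(u, u, np.eye(2), np.zeros((2, 2)), 2) == 1.0

    def test_genetic_update_zero_blup_is_trace_only(self):
        z = np.zeros(3)
        K_inv = np.diag([1.0, 2.0, 4.0])
        Cb = np.diag([0.5, 0.25, 0.125])
        val = em_update_genetic(z, z, K_inv, Cb, 3)
        assert val == pytest.approx((0.5 + 0.5 + 0.5) / 3)

    def test_genetic_update_symmetric_in_pair(self):
        rng = np.random.default_rng(5)
        K_inv = _random_pd(4, rng)
        Cb = rng.standard_normal((4, 4))
        u1, u2 = rng.standard_normal(4), rng.standard_normal(4)
        a = em_update_genetic(u1, u2, K_inv, Cb, 4)
        b = em_update_genetic(u2, u1, K_inv, Cb.T, 4)
        assert a == pytest.approx(b)

    def test_genetic_update_rejects_bad_levels(self):
        with pytest.raises(ValueError):
            em_update_genetic(np.zeros(2), np.zeros(2), np.eye(2), np.eye(2), 0)

    def test_residual_update_single_trait_plug_in(self):
        """e'e = 10, trace term = 2, n = 4 records -> update 3.0."""
        e = np.array([3.0, 1.0, 0.0, 0.0])
        W = np.eye(4)
        C_inv = np.diag([0.5, 0.5, 0.5, 0.5])
        R = em_update_residual(e, W, C_inv, np.zeros(4, int), np.arange(4), 1)
        assert R[0, 0] == pytest.approx(3.0)

    def test_residual_update_never_collapses_on_perfect_fit(self):
        e = np.zeros(3)
        W = np.eye(3)
        C_inv = np.eye(3) * 0.2
        R = em_update_residual(e, W, C_inv, np.zeros(3, int), np.arange(3), 1)
        assert R[0, 0] > 0

    def test_fast_residual_path_matches_reference(self):
        """The O(n) gather used inside the EM loop reproduces the dense
        W C^-1 W' reference computation, including with missing cells."""
        rng = np.random.default_rng(8)
        n, t = 7, 2
        A = _random_pd(n, rng)
        D = _random_pd(n, rng)
        Y = rng.standard_normal((n, t))
        Y[0, 1] = np.nan
        Y[3, 0] = np.nan
        vc = VarianceComponents(
            V_alpha=_random_pd(t, rng), R=_random_pd(t, rng), V_delta=_random_pd(t, rng)
        )
        ws = _Workspace(Y, np.linalg.inv(A), np.linalg.inv(D))
        C, rhs, _ = ws.build(vc)
        C_inv = np.linalg.inv(C)
        sol = C_inv @ rhs
        vc_new = ws.em_step(vc, C_inv, sol)

        beta, alpha, delta = ws.split(sol)
        y_st, W, rec_t, rec_i = dense_design(Y, True)
        E = Y - beta - alpha.T - delta.T
        e_st = E[rec_i, rec_t]
        R_ref = em_update_residual(e_st, W, C_inv, rec_t, rec_i, t)
        np.testing.assert_allclose(vc_new.R, R_ref, atol=1e-10)


class TestFitGBLUP:
    def test_fit_deterministic(self, small_study):
        spec = ModelSpec("MV-A", small_study.truth.trait_names[:2])
        kwargs = dict(spec=spec, tol=1e-4, max_iter=40)
        f1 = fit_gblup(small_study.phenotypes, small_study.A, **kwargs)
        f2 = fit_gblup(small_study.phenotypes, small_study.A, **kwargs)
        np.testing.assert_array_equal(f1.alpha_hat, f2.alpha_hat)
        np.testing.assert_array_equal(f1.vc.V_alpha, f2.vc.V_alpha)

    def test_loglik_monotone_on_study(self, small_study):
        spec = ModelSpec("MV-AD", small_study.truth.trait_names[:3])
        fit = fit_gblup(
            small_study.phenotypes, small_study.A, D=small_study.D,
            spec=spec, tol=1e-4, max_iter=60,
        )
        assert np.all(np.diff(fit.loglik_trace) > -1e-6)

    def test_univariate_batch_collects_per_trait_fits(self, small_study):
        spec = ModelSpec("UV-A", small_study.truth.trait_names[:2])
        fit = fit_gblup(small_study.phenotypes, small_study.A, spec=spec,
                        tol=1e-4, max_iter=60)
        assert len(fit.trait_fits) == 2
        assert fit.delta_hat.any() == False  # noqa: E712 - zeros for A variant
        assert fit.vc.V_alpha[0, 1] == 0.0

    def test_single_em_iteration_of_diagonal_mv_matches_uv(self, small_study):
        """From a diagonal state, one EM sweep of the MV model updates the
        diagonal variance entries exactly as the per-trait UV analyses."""
        traits = small_study.truth.trait_names[:2]
        Y = small_study.phenotypes.to_frame()[traits].to_numpy()
        diag_init = VarianceComponents(
            V_alpha=np.diag([5.0, 8.0]), R=np.diag([4.0, 6.0])
        )
        mv = fit_gblup(Y, small_study.A, spec=ModelSpec("MV-A", traits),
                       init_vc=diag_init, tol=0, max_iter=1)
        for ti in range(2):
            uv_init = VarianceComponents(
                V_alpha=[[diag_init.V_alpha[ti, ti]]], R=[[diag_init.R[ti, ti]]]
            )
            uv = fit_gblup(Y[:, ti], small_study.A,
                           spec=ModelSpec("UV-A", [traits[ti]]),
                           init_vc=uv_init, tol=0, max_iter=1)
            assert mv.vc.V_alpha[ti, ti] == pytest.approx(
                uv.vc.V_alpha[0, 0], rel=1e-8
            )
            assert mv.vc.R[ti, ti] == pytest.approx(uv.vc.R[0, 0], rel=1e-8)

    def test_missing_records_still_predicted(self, small_study):
        """An individual without phenotypes keeps a genetic prediction."""
        traits = small_study.truth.trait_names[:2]
        Y = small_study.phenotypes.to_frame()[traits].to_numpy().copy()
        Y[5, :] = np.nan
        spec = ModelSpec("MV-A", traits)
        fit = fit_gblup(Y, small_study.A, spec=spec, tol=1e-4, max_iter=40)
        assert np.isfinite(fit.predict()[5]).all()
        # shrinkage: held-out BLUP magnitude below the largest observed one
        assert np.abs(fit.alpha_hat[5]).max() <= np.abs(fit.alpha_hat).max()

    def test_blup_frame_and_report(self, small_study):
        spec = ModelSpec("UV-AD", [small_study.truth.trait_names[0]])
        fit = fit_gblup(small_study.phenotypes, small_study.A, D=small_study.D,
                        spec=spec, tol=1e-3, max_iter=30)
        frame = fit.blup_frame()
        assert set(frame.columns) == {"individual", "trait", "alpha", "delta", "g"}
        assert len(frame) == small_study.hybrids.n_individuals
        d = fit.to_json_dict()
        assert d["variant"] == "UV-AD" and "V_delta" in d
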