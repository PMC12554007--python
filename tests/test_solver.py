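"""Proximal operator, backtracking, penalized fits and the lambda path."""

import numpy as np
import pytest

from methvc.basis import PenaltyMatrices, build_basis, compose_penalty
from methvc.likelihood import (
    CoefficientSet,
    assemble_design,
    neg2_loglik_from_pi,
    predict_pi,
)
from methvc.solver import (
    SolverConfig,
    backtracking_step,
    compute_lambda_max,
    default_tau,
    fit_intercept_only,
    fit_penalized,
    prox_group,
    solve_path,
)

from .conftest import random_dataset
from .oracles import (
    glm_binomial_reference,
    penalized_objective,
    solve_penalized_reference,
)


class TestProxGroup:
    def test_shrinks_group_toward_zero(self):
        u = np.array([9.0, 9.0, 2.0, 0.0])  # intercept K=2, one group (2, 0)
        out = prox_group(u, threshold=1.0, K=2)
        np.testing.assert_allclose(out, [9.0, 9.0, 1.0, 0.0])

    def test_small_group_truncated_to_zero(self):
        u = np.array([1.0, 1.0, 0.3, 0.4])
        out = prox_group(u, threshold=0.5, K=2)
        np.testing.assert_array_equal(out[2:], 0.0)

    def test_intercept_passes_through(self):
        u = np.array([5.0, -4.0, 1.0, 1.0])
        out = prox_group(u, threshold=100.0, K=2)
        np.testing.assert_array_equal(out[:2], u[:2])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prox_group(np.ones(4), threshold=-0.1, K=2)

    def test_matches_numeric_prox_minimizer(self):
        # minimize (1/2t)||u - eta||^2 + lam sum ||eta_p|| on 2 groups
        from scipy.optimize import minimize

        rng = np.random.default_rng(2)
        K, lam, t = 3, 0.8, 0.5
        u = rng.standard_normal(3 * K)  # intercept + 2 groups
        out = prox_group(u, threshold=t * lam, K=K)

        def obj(e):
            pen = sum(
                np.sqrt((e[K * (p + 1):K * (p + 2)] ** 2).sum() + 1e-16)
                for p in range(2)
            )
            return ((u - e) ** 2).sum() / (2 * t) + lam * pen

        ref = minimize(obj, u, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(out, ref.x, atol=1e-5)


class TestBacktracking:
    def _setup(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, n_samples=6, n_snps=2, n_cpgs=8)
        basis = build_basis(ds.positions, 4)
        mats = PenaltyMatrices.from_basis(basis, ds.M)
        pen = compose_penalty(mats, alpha=0.3, lam=50.0, P=2)
        design = assemble_design(ds, basis, pen)
        return ds, design, pen

    def test_accepted_step_satisfies_majorization_inequality(self):
        from methvc.likelihood import gradient_eta, neg2_loglik_eta

        ds, design, pen = self._setup()
        rng = np.random.default_rng(0)
        eta = 0.1 * rng.standard_normal(design.n_coef)
        config = SolverConfig(t_init=1.0)
        smooth = lambda e: neg2_loglik_eta(e, design, ds)
        grad = gradient_eta(eta, design, ds)
        t, eta_new, val = backtracking_step(
            eta, config, smooth, grad, smooth(eta), pen.lam, 4, None, 1.0
        )
        G = (eta - eta_new) / t
        lhs = smooth(eta - t * G)
        rhs = smooth(eta) - t * grad @ G + 0.5 * t * (G @ G)
        assert lhs <= rhs + 1e-9 * max(1.0, abs(rhs))

    def test_quadratic_surrogate_accepts_inverse_curvature_step(self):
        # 1-d quadratic c/2 x^2: any t <= 1/c passes immediately
        c = 4.0
        smooth = lambda e: 0.5 * c * float(e @ e)
        eta = np.array([2.0, 0.0, 0.0, 0.0])
        grad = c * eta
        config = SolverConfig(t_init=1.0 / c)
        t, eta_new, _ = backtracking_step(
            eta, config, smooth, grad, smooth(eta), 0.0, 2, None, 1.0 / c
        )
        assert t == pytest.approx(1.0 / c)

    def test_fixed_point_returns_unchanged(self):
        smooth = lambda e: float(e @ e)  # minimum at 0 with zero gradient
        eta = np.zeros(4)
        config = SolverConfig(t_init=1.0)
        t, eta_new, _ = backtracking_step(
            eta, config, smooth, np.zeros(4), 0.0, 1.0, 2, None, 1.0
        )
        np.testing.assert_array_equal(eta_new, eta)


class TestFitIntercept:
    def test_symmetric_null_gives_zero_curve(self):
        rng = np.random.default_rng(9)
        positions = np.sort(rng.choice(400, 10, replace=False)).astype(float)
        ds_rec = dict(
            sample_idx=np.repeat(np.arange(5), 10),
            positions=np.tile(positions, 5),
            total=np.full(50, 10.0),
            meth=np.full(50, 5.0),
            genotypes=np.zeros((5, 1)),
        )
        from methvc.data import RegionDataset

        ds = RegionDataset(**ds_rec)
        basis = build_basis(positions, 4)
        fit = fit_intercept_only(ds, basis)
        assert np.abs(fit.theta[0]).max() < 1e-4
        assert not np.any(fit.theta[1:])

    def test_matches_statsmodels_glm(self, tiny_setup):
        ds, basis, mats = tiny_setup
        fit = fit_intercept_only(ds, basis)
        pi_ours = predict_pi(fit, ds, basis)
        B = basis.evaluate(ds.positions)
        pi_ref, _ = glm_binomial_reference(B, ds.meth, ds.total)
        np.testing.assert_allclose(pi_ours, pi_ref, atol=1e-5)

    def test_deterministic(self, tiny_setup):
        ds, basis, mats = tiny_setup
        f1 = fit_intercept_only(ds, basis)
        f2 = fit_intercept_only(ds, basis)
        np.testing.assert_array_equal(f1.theta, f2.theta)


class TestLambdaMax:
    def test_brackets_selection_boundary(self, signal_region):
        ds = signal_region.dataset
        basis = build_basis(ds.positions, 6)
        mats = PenaltyMatrices.from_basis(basis, ds.M)
        pen = compose_penalty(mats, alpha=0.5, lam=0.0, P=ds.P)
        design = assemble_design(ds, basis, pen)
        intercept = fit_intercept_only(ds, basis)
        lam_max = compute_lambda_max(ds, design, pen, intercept)
        for scale, expect_any in ((1.001, False), (0.95, True)):
            pen_s = compose_penalty(mats, 0.5, scale * lam_max, ds.P)
            design.penalty = pen_s
            fit = fit_penalized(ds, design, pen_s, init=intercept)
            assert bool(fit.selected) == expect_any

    def test_zero_genotypes_give_zero(self, tiny_setup):
        ds, basis, mats = tiny_setup
        from methvc.data import RegionDataset

        ds0 = RegionDataset(
            sample_idx=ds.sample_idx, positions=ds.positions,
            meth=ds.meth, total=ds.total,
            genotypes=np.zeros_like(ds.genotypes),
        )
        pen = compose_penalty(mats, alpha=0.2, lam=0.0, P=ds0.P)
        design = assemble_design(ds0, basis, pen)
        intercept = fit_intercept_only(ds0, basis)
        assert compute_lambda_max(ds0, design, pen, intercept) == 0.0

    def test_identity_metric_reduces_to_gradient_norm(self, tiny_setup):
        ds, basis, mats = tiny_setup
        pen = compose_penalty(mats, alpha=0.0, lam=0.0, P=ds.P, identity=True)
        design = assemble_design(ds, basis, pen)
        intercept = fit_intercept_only(ds, basis)
        lam_max = compute_lambda_max(ds, design, pen, intercept)
        from scipy.special import expit

        pi0 = expit(design.B @ intercept.theta[0])
        resid = ds.meth - ds.total * pi0
        Zrec = ds.genotypes[ds.sample_idx]
        norms = [
            np.linalg.norm(2.0 * design.B.T @ (resid * Zrec[:, p]))
            for p in range(ds.P)
        ]
        assert lam_max == pytest.approx(max(norms), rel=1e-12)


class TestFitPenalized:
    @pytest.mark.parametrize("alpha,identity", [
        (0.0, False), (0.5, False), (0.99, False), (0.0, True),
    ])
    def test_objective_matches_reference_solver(self, tiny_setup, alpha, identity):
        ds, basis, mats = tiny_setup
        pen0 = compose_penalty(mats, alpha, 0.0, ds.P, identity=identity)
        design = assemble_design(ds, basis, pen0)
        intercept = fit_intercept_only(ds, basis)
        lam_max = compute_lambda_max(ds, design, pen0, intercept)
        lam = 0.1 * lam_max
        pen = compose_penalty(mats, alpha, lam, ds.P, identity=identity)
        design.penalty = pen
        fit = fit_penalized(ds, design, pen, init=intercept,
                            config=SolverConfig(tol=1e-12, max_iter=100_000))
        obj = fit.objective_trace[-1]
        _, obj_ref = solve_penalized_reference(
            design.Xt, ds.meth, ds.total, lam, basis.K, x0=fit.eta
        )
        assert obj == pytest.approx(obj_ref, rel=1e-4)

    def test_unpenalized_limit_matches_glm(self, tiny_setup):
        ds, basis, mats = tiny_setup
        pen = compose_penalty(mats, alpha=0.5, lam=0.0, P=ds.P)
        design = assemble_design(ds, basis, pen)
        fit = fit_penalized(
            ds, design, pen, init=fit_intercept_only(ds, basis),
            config=SolverConfig(tol=1e-12, max_iter=20000),
        )
        B = design.Xt  # lam = 0: the MLE in any coordinates
        pi_ref, _ = glm_binomial_reference(B, ds.meth, ds.total)
        pi_ours = predict_pi(fit.coefs, ds, basis)
        np.testing.assert_allclose(pi_ours, pi_ref, atol=1e-5)

    def test_monotone_objective_trace(self, tiny_setup):
        ds, basis, mats = tiny_setup
        pen0 = compose_penalty(mats, 0.5, 0.0, ds.P)
        design = assemble_design(ds, basis, pen0)
        intercept = fit_intercept_only(ds, basis)
        lam = 0.2 * compute_lambda_max(ds, design, pen0, intercept)
        pen = compose_penalty(mats, 0.5, lam, ds.P)
        design.penalty = pen
        fit = fit_penalized(ds, design, pen)
        assert np.all(np.diff(fit.objective_trace) <= 1e-9)

    def test_kkt_conditions_at_convergence(self, signal_region):
        ds = signal_region.dataset
        basis = build_basis(ds.positions, 6)
        mats = PenaltyMatrices.from_basis(basis, ds.M)
        pen0 = compose_penalty(mats, 0.5, 0.0, ds.P)
        design = assemble_design(ds, basis, pen0)
        intercept = fit_intercept_only(ds, basis)
        lam = 0.3 * compute_lambda_max(ds, design, pen0, intercept)
        pen = compose_penalty(mats, 0.5, lam, ds.P)
        design.penalty = pen
        fit = fit_penalized(ds, design, pen, init=intercept,
                            config=SolverConfig(tol=1e-12, max_iter=100_000))
        from methvc.likelihood import gradient_eta

        g = gradient_eta(fit.eta, design, ds)
        K = basis.K
        for p in range(ds.P):
            gp = g[(p + 1) * K:(p + 2) * K]
            eta_p = fit.eta[(p + 1) * K:(p + 2) * K]
            if np.any(eta_p):
                resid = gp + lam * eta_p / np.linalg.norm(eta_p)
                assert np.linalg.norm(resid) <= 1e-3 * lam
            else:
                assert np.linalg.norm(gp) <= lam * (1 + 1e-3)


class TestSolvePath:
    def test_path_structure_and_first_fit_empty(self, tiny_setup):
        ds, basis, mats = tiny_setup
        path = solve_path(ds, basis, mats, alpha=0.5, L=10, tau=0.01)
        assert path.lambdas.size == 10
        ratios = path.lambdas[1:] / path.lambdas[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)
        assert path.fits[0].selected == []
        assert np.all(np.diff(path.lambdas) < 0)

    def test_default_path_length_is_100(self):
        from methvc.solver import DEFAULT_PATH_LENGTH

        assert DEFAULT_PATH_LENGTH == 100

    def test_default_tau_rule(self):
        assert default_tau(M=100, P=20, K=10) == 0.01   # M < (P+1)K
        assert default_tau(M=5000, P=20, K=10) == 0.001

    def test_warm_and_cold_start_agree(self, tiny_setup):
        ds, basis, mats = tiny_setup
        tight = SolverConfig(tol=1e-12, max_iter=100_000)
        path = solve_path(ds, basis, mats, alpha=0.3, L=8, tau=0.05,
                          config=tight)
        # cold start at the middle lambda
        lam = path.lambdas[4]
        pen = compose_penalty(mats, 0.3, lam, ds.P)
        design = assemble_design(ds, basis, pen)
        cold = fit_penalized(ds, design, pen, config=tight)
        warm_obj = path.fits[4].objective_trace[-1]
        assert cold.objective_trace[-1] == pytest.approx(warm_obj, rel=1e-6)

    def test_group_norms_continuous_along_path(self, tiny_setup):
        ds, basis, mats = tiny_setup
        path = solve_path(ds, basis, mats, alpha=0.0, L=25, tau=0.01,
                          config=SolverConfig(tol=1e-10))
        K = basis.K
        norms = np.array([
            np.linalg.norm(f.eta[K:].reshape(-1, K), axis=1) for f in path.fits
        ])
        jumps = np.abs(np.diff(norms, axis=0))
        scale = norms.max() + 1e-12
        assert jumps.max() <= 0.35 * scale  # no discontinuous jumps
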