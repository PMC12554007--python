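"""Independent reference computations used only by the test suite.

These deliberately avoid the package's own code paths: integrals are done
by dense trapezoid rules, optima by a general-purpose quasi-Newton solver
on an epsilon-smoothed objective, and GLM fits by statsmodels.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


def trapezoid_gram(func_values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gram matrix of columns of ``func_values`` by dense trapezoid rule."""
    w = np.gradient(grid)
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return (func_values * w[:, None]).T @ func_values


def fd_second_derivative(f, t, h=1e-5):
    """Central finite-difference second derivative of a callable."""
    return (f(t + h) - 2.0 * f(t) + f(t - h)) / h**2


def fd_gradient(f, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def neg2_loglik_ref(meth, total, pi):
    pi = np.clip(pi, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(meth * np.log(pi) + (total - meth) * np.log(1 - pi)))


def penalized_objective(eta, Xt, meth, total, lam, K):
    """Exact group-penalized twice-negative log-likelihood at eta."""
    pi = expit(Xt @ eta)
    groups = eta[K:].reshape(-1, K)
    return neg2_loglik_ref(meth, total, pi) + lam * np.linalg.norm(
        groups, axis=1).sum()


def solve_penalized_reference(Xt, meth, total, lam, K, eps=1e-9, x0=None):
    """Reference minimizer of the group-penalized problem.

    Minimizes the smooth surrogate with ``sqrt(||eta_p||^2 + eps)`` in
    place of the group norm by L-BFGS, then reports the exact objective at
    the surrogate optimum.  For eps small the exact objective at the
    surrogate solution is within O(P * lam * sqrt(eps)) of the true
    minimum.
    """
    D = Xt.shape[1]

    def fun(eta):
        pi = expit(Xt @ eta)
        pi = np.clip(pi, 1e-10, 1 - 1e-10)
        ll = -2.0 * np.sum(meth * np.log(pi) + (total - meth) * np.log(1 - pi))
        groups = eta[K:].reshape(-1, K)
        pen = lam * np.sqrt((groups**2).sum(axis=1) + eps).sum()
        return ll + pen

    def jac(eta):
        pi = expit(Xt @ eta)
        g = -2.0 * (Xt.T @ (meth - total * pi))
        groups = eta[K:].reshape(-1, K)
        norms = np.sqrt((groups**2).sum(axis=1) + eps)
        g[K:] += (lam * groups / norms[:, None]).ravel()
        return g

    x0 = np.zeros(D) if x0 is None else x0
    res = minimize(fun, x0, jac=jac, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-10})
    obj = penalized_objective(res.x, Xt, meth, total, lam, K)
    return res.x, obj


def glm_binomial_reference(B, meth, total):
    """Unpenalized binomial GLM fit via statsmodels; returns probabilities."""
    import statsmodels.api as sm

    endog = np.column_stack([meth, total - meth])
    fit = sm.GLM(endog, B, family=sm.families.Binomial()).fit()
    return np.asarray(fit.predict(B)), np.asarray(fit.params)
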