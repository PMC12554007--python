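"""Scikit-learn style estimators for sparse smooth mQTL mapping.

``SparseSmoothVCM`` fits the penalized binomial varying-coefficient model
at one (lambda, alpha); ``SparseSmoothVCMCV`` runs the full pipeline —
lambda path from the analytic lambda_max, (alpha, lambda) grid search by
by-individual K-fold cross-validation with the min-deviance or 1-SE rule,
and an optional adaptive reweighting pass.  Both follow scikit-learn
conventions (``get_params``/``set_params``, fitted attributes with a
trailing underscore) with a :class:`~methvc.data.RegionDataset` playing
the role of X; ``y`` is ignored, since the binomial outcome lives inside
the dataset's records.

The ``penalty`` parameter picks the regularizer family:

- ``"ssp"``: the full sparsity-smoothness penalty with metric
  ``H_alpha = (1 - alpha) Omega1 + alpha Omega2``;
- ``"ssp0"``: the sparsity-only special case (alpha pinned at 0, metric
  ``Omega1``);
- ``"glasso"``: plain group LASSO on the basis coefficients (identity
  metric).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .basis import PenaltyMatrices, build_basis, compose_penalty
from .data import RegionDataset
from .likelihood import (
    assemble_design,
    coefficient_functions,
    predict_pi,
)
from .solver import (
    SolverConfig,
    compute_lambda_max,
    fit_intercept_only,
    fit_penalized,
    solve_path,
)
from .tuning import (
    DEFAULT_ALPHA_GRID,
    adaptive_weights,
    basis_dimension_rule,
    cross_validate,
    fit_adaptive,
    make_folds,
)

_PENALTIES = ("ssp", "ssp0", "glasso")


def _check_penalty(penalty: str) -> None:
    if penalty not in _PENALTIES:
        raise ValueError(f"penalty must be one of {_PENALTIES}, got {penalty!r}")


class _VCMBase(BaseEstimator):
    """Shared plumbing: basis construction and prediction."""

    def _build_basis(self, dataset: RegionDataset):
        K = self.K
        if K is None:
            K = basis_dimension_rule(np.unique(dataset.positions).size).snp
        self.basis_ = build_basis(dataset.positions, K)
        self.matrices_ = PenaltyMatrices.from_basis(self.basis_, dataset.M)

    def predict(self, dataset: RegionDataset) -> np.ndarray:
        """Fitted methylation probabilities at the dataset's records."""
        self._check_fitted()
        return predict_pi(self.coefs_, dataset, self.basis_)

    def coefficient_curves(self, grid) -> np.ndarray:
        """beta_p on a grid of raw bp positions; rows 0..P (0 = baseline)."""
        self._check_fitted()
        return coefficient_functions(self.coefs_, self.basis_, grid)

    def _check_fitted(self):
        if not hasattr(self, "coefs_"):
            raise RuntimeError("estimator is not fitted")

    def score(self, dataset: RegionDataset, y=None) -> float:
        """Negative mean deviance (higher is better, sklearn convention)."""
        from .likelihood import neg2_loglik_from_pi

        pi = self.predict(dataset)
        return -neg2_loglik_from_pi(dataset.meth, dataset.total, pi) / dataset.M


class SparseSmoothVCM(_VCMBase):
    """Penalized fit at a single (lambda, alpha).

    Parameters
    ----------
    lam : float or "max"
        Penalty level; "max" uses the analytic lambda_max (every SNP group
        zero).  ``lam_scale`` multiplies either choice.
    alpha : float in [0, 1)
        Smoothness mixing weight (ignored for the group-LASSO penalty).
    penalty : {"ssp", "ssp0", "glasso"}
    K : int or None
        Basis dimension; None applies the regional dimension rule.
    """

    def __init__(
        self,
        lam="max",
        lam_scale: float = 1.0,
        alpha: float = 0.5,
        penalty: str = "ssp",
        K: Optional[int] = 10,
        tol: float = 1e-8,
        max_iter: int = 5000,
        t_init: Optional[float] = None,
    ):
        self.lam = lam
        self.lam_scale = lam_scale
        self.alpha = alpha
        self.penalty = penalty
        self.K = K
        self.tol = tol
        self.max_iter = max_iter
        self.t_init = t_init

    def fit(self, dataset: RegionDataset, y=None):
        _check_penalty(self.penalty)
        alpha = 0.0 if self.penalty == "ssp0" else self.alpha
        identity = self.penalty == "glasso"
        self._build_basis(dataset)
        config = SolverConfig(tol=self.tol, max_iter=self.max_iter, t_init=self.t_init)
        pen0 = compose_penalty(self.matrices_, alpha, 0.0, dataset.P, identity=identity)
        design = assemble_design(dataset, self.basis_, pen0)
        intercept = fit_intercept_only(dataset, self.basis_)
        self.lambda_max_ = compute_lambda_max(dataset, design, pen0, intercept)
        lam = self.lambda_max_ if self.lam == "max" else float(self.lam)
        lam *= self.lam_scale
        pen = compose_penalty(self.matrices_, alpha, lam, dataset.P, identity=identity)
        design.penalty = pen
        fit = fit_penalized(dataset, design, pen, init=intercept, config=config)
        self.fit_result_ = fit
        self.coefs_ = fit.coefs
        self.selected_ = list(fit.selected)
        self.lambda_ = lam
        self.alpha_ = alpha
        self.n_iter_ = fit.n_iter
        return self


class SparseSmoothVCMCV(_VCMBase):
    """Cross-validated pipeline with optional adaptive reweighting.

    The recommended configuration for mQTL mapping is the adaptive
    penalty with the 1-SE selection rule (``adaptive=True,
    rule="one_se"``), which consistently trims false positives while
    keeping estimation and prediction accuracy.
    """

    def __init__(
        self,
        penalty: str = "ssp",
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        n_lambda: int = 100,
        tau: Optional[float] = None,
        n_folds: int = 5,
        rule: str = "one_se",
        adaptive: bool = False,
        K: Optional[int] = 10,
        tol: float = 1e-8,
        max_iter: int = 5000,
        random_state: int = 0,
    ):
        self.penalty = penalty
        self.alpha_grid = alpha_grid
        self.n_lambda = n_lambda
        self.tau = tau
        self.n_folds = n_folds
        self.rule = rule
        self.adaptive = adaptive
        self.K = K
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, dataset: RegionDataset, y=None):
        _check_penalty(self.penalty)
        alpha_grid = (
            (0.0,) if self.penalty in ("ssp0", "glasso")
            else tuple(self.alpha_grid)
        )
        identity = self.penalty == "glasso"
        self._build_basis(dataset)
        config = SolverConfig(tol=self.tol, max_iter=self.max_iter)
        folds = make_folds(dataset, self.n_folds, self.random_state)
        cv = cross_validate(
            dataset, self.basis_, self.matrices_, alpha_grid=alpha_grid,
            identity=identity, L=self.n_lambda, tau=self.tau,
            n_folds=self.n_folds, seed=self.random_state, config=config,
            folds=folds,
        )
        self.cv_ = cv
        a, l = cv.chosen_index(self.rule)
        fit = cv.full_paths[a].fits[l]
        self.initial_fit_ = fit

        if self.adaptive:
            w = adaptive_weights(fit, self.matrices_)
            self.adaptive_weights_ = w
            adp = fit_adaptive(
                dataset, self.basis_, self.matrices_, w,
                alpha_grid=alpha_grid, L=self.n_lambda, tau=self.tau,
                n_folds=self.n_folds, seed=self.random_state,
                rule=self.rule, config=config, folds=folds,
            )
            self.adaptive_cv_ = adp.cv
            fit = adp.fit

        self.fit_result_ = fit
        self.coefs_ = fit.coefs
        self.selected_ = list(fit.selected)
        self.lambda_ = fit.lam
        self.alpha_ = fit.alpha
        self.lambda_max_ = cv.full_paths[a].lambda_max
        return self

    def selection_summary(self) -> dict:
        self._check_fitted()
        return {
            "penalty": self.penalty,
            "rule": self.rule,
            "adaptive": bool(self.adaptive),
            "lambda": float(self.lambda_),
            "alpha": float(self.alpha_),
            "selected": [int(s) for s in self.selected_],
            "n_selected": len(self.selected_),
        }
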