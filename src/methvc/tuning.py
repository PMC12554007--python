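"""Tuning-parameter selection by cross-validation and the adaptive refit.

(lambda, alpha) are chosen by K-fold cross-validation over a per-alpha
lambda path anchored at the full-data lambda_max.  Folds split
*individuals*, not records: all records of a sample share its genotype and
are dependent, so record-level splits would leak.  Validation error is the
mean deviance ``(1/M_o) sum -2[Y log pihat + (X-Y) log(1-pihat)]`` over the
held-out records; its SE is the standard deviation of per-fold means
divided by sqrt(n_folds).  Besides the minimizer, the one-standard-error
rule picks, at the minimizing alpha, the largest lambda whose mean error is
within one SE of the minimum — favoring parsimony.

The adaptive variant reweights the penalty per covariate with
``w1p = 1/sqrt(J1(betahat_p))`` and ``w2p = 1/sqrt(J2(betahat_p))`` from an
initial ordinary fit; covariates whose initial estimate is identically
zero get infinite weight and are excluded outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .basis import NaturalCubicBasis, PenaltyMatrices, compose_penalty
from .data import RegionDataset
from .likelihood import CoefficientSet, neg2_loglik_from_pi, predict_pi
from .solver import (
    DEFAULT_PATH_LENGTH,
    FitResult,
    PathResult,
    SolverConfig,
    default_tau,
    fit_intercept_only,
    solve_path,
)

logger = logging.getLogger("methvc")

# 12-point alpha grid used for the simulation studies
DEFAULT_ALPHA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.99)


def make_folds(dataset: RegionDataset, n_folds: int, seed: int) -> np.ndarray:
    """Random partition of individuals into folds of near-equal size.

    Returns an (N,) array of fold labels; deterministic given the seed.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > dataset.N:
        raise ValueError(f"cannot split {dataset.N} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(dataset.N)
    assignment = np.empty(dataset.N, dtype=int)
    assignment[order] = np.arange(dataset.N) % n_folds
    return assignment


@dataclass
class CVResult:
    """Mean validation deviance and its SE over the (alpha, lambda) grid."""

    alphas: np.ndarray            # (A,)
    lambdas: np.ndarray           # (A, L) per-alpha paths
    mean_cv_error: np.ndarray     # (A, L)
    se_cv_error: np.ndarray       # (A, L)
    fold_assignment: np.ndarray   # (N,)
    seed: int
    full_paths: list[PathResult]  # full-data paths per alpha

    def _min_index(self) -> tuple[int, int]:
        flat = np.argmin(self.mean_cv_error)
        return np.unravel_index(flat, self.mean_cv_error.shape)

    @property
    def chosen_min(self) -> tuple[float, float]:
        a, l = self._min_index()
        return float(self.lambdas[a, l]), float(self.alphas[a])

    @property
    def chosen_1se(self) -> tuple[float, float]:
        a, l = self._min_index()
        bound = self.mean_cv_error[a, l] + self.se_cv_error[a, l]
        ok = np.flatnonzero(self.mean_cv_error[a, : l + 1] <= bound)
        return float(self.lambdas[a, ok[0]]), float(self.alphas[a])

    def chosen_index(self, rule: str) -> tuple[int, int]:
        a, l = self._min_index()
        if rule == "min":
            return a, l
        if rule == "one_se":
            bound = self.mean_cv_error[a, l] + self.se_cv_error[a, l]
            return a, int(np.flatnonzero(self.mean_cv_error[a, : l + 1] <= bound)[0])
        raise ValueError(f"unknown selection rule {rule!r}")

    def to_frame(self):
        import pandas as pd

        rows = []
        for a, alpha in enumerate(self.alphas):
            for l in range(self.lambdas.shape[1]):
                rows.append(
                    (alpha, self.lambdas[a, l], self.mean_cv_error[a, l],
                     self.se_cv_error[a, l])
                )
        return pd.DataFrame(rows, columns=["alpha", "lambda", "mean_error", "se"])


def select_lambda(cv: CVResult, rule: str = "one_se") -> tuple[float, float]:
    """Return the chosen (lambda, alpha) under the min or 1-SE rule."""
    if cv.mean_cv_error.size == 0:
        raise ValueError("empty cross-validation grid")
    if rule == "min":
        return cv.chosen_min
    if rule == "one_se":
        return cv.chosen_1se
    raise ValueError(f"unknown selection rule {rule!r}")


def cross_validate(
    dataset: RegionDataset,
    basis: NaturalCubicBasis,
    matrices: PenaltyMatrices,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    weights=None,
    identity: bool = False,
    L: int = DEFAULT_PATH_LENGTH,
    tau: Optional[float] = None,
    n_folds: int = 5,
    seed: int = 0,
    config: Optional[SolverConfig] = None,
    folds: Optional[np.ndarray] = None,
) -> CVResult:
    """Grid search over (alpha, lambda) with by-individual K-fold CV.

    For each alpha the lambda path is derived once from the full data and
    reused across folds, so fold errors are comparable point by point.
    Full-data paths are fitted as well (they provide the final coefficient
    estimates at the chosen grid point).
    """
    alphas = np.asarray(list(alpha_grid), dtype=float)
    config = config or SolverConfig()
    if folds is None:
        folds = make_folds(dataset, n_folds, seed)
    else:
        folds = np.asarray(folds, dtype=int)
        n_folds = int(folds.max()) + 1
    if tau is None:
        tau = default_tau(dataset.M, dataset.P, basis.K)

    intercept_full = fit_intercept_only(dataset, basis)
    full_paths: list[PathResult] = []
    lambda_grid = np.empty((alphas.size, L))
    for a, alpha in enumerate(alphas):
        path = solve_path(
            dataset, basis, matrices, alpha, weights=weights,
            identity=identity, L=L, tau=tau, config=config,
            intercept_fit=intercept_full,
        )
        full_paths.append(path)
        lambda_grid[a] = (
            path.lambdas if path.lambdas.size == L
            else np.resize(path.lambdas, L)
        )

    fold_errors = np.empty((alphas.size, L, n_folds))
    for o in range(n_folds):
        train = dataset.subset_records(folds[dataset.sample_idx] != o)
        valid = dataset.subset_records(folds[dataset.sample_idx] == o)
        dropped = np.all(train.genotypes[np.unique(train.sample_idx)] == 0, axis=0)
        if dropped.any():
            logger.info(
                "fold %d: %d SNPs constant-zero in training, unselectable there",
                o, int(dropped.sum()),
            )
        intercept_tr = fit_intercept_only(train, basis)
        for a, alpha in enumerate(alphas):
            path = solve_path(
                train, basis, matrices, alpha, weights=weights,
                identity=identity, config=config,
                lambdas=lambda_grid[a], intercept_fit=intercept_tr,
            )
            for l, fit in enumerate(path.fits):
                pi_val = predict_pi(fit.coefs, valid, basis)
                fold_errors[a, l, o] = (
                    neg2_loglik_from_pi(valid.meth, valid.total, pi_val) / valid.M
                )

    mean_err = fold_errors.mean(axis=2)
    se_err = fold_errors.std(axis=2, ddof=1) / np.sqrt(n_folds)
    return CVResult(
        alphas=alphas,
        lambdas=lambda_grid,
        mean_cv_error=mean_err,
        se_cv_error=se_err,
        fold_assignment=folds,
        seed=seed,
        full_paths=full_paths,
    )


@dataclass
class AdaptiveWeights:
    """Per-covariate penalty weights derived from an initial fit."""

    w1: np.ndarray        # (P,) 1/sqrt(J1); inf for excluded covariates
    w2: np.ndarray        # (P,) 1/sqrt(J2), capped for near-linear estimates
    excluded: np.ndarray  # (P,) bool

    def as_pairs(self) -> np.ndarray:
        return np.column_stack([self.w1, self.w2])


def adaptive_weights(
    initial: FitResult, matrices: PenaltyMatrices, eps: float = 1e-8
) -> AdaptiveWeights:
    """Weights w1 = 1/sqrt(J1), w2 = 1/sqrt(J2) from an ordinary fit.

    Covariates with a zero initial estimate (J1 = 0) are excluded.  A
    near-linear initial estimate has J2 ~ 0 while J1 > 0; its w2 is capped
    at 1/sqrt(eps * J1) so the reweighted metric stays positive definite
    without excluding a genuinely linear effect.
    """
    theta = initial.coefs.theta
    P = theta.shape[0] - 1
    omega1 = matrices.omega1
    omega2 = matrices.omega2
    w1 = np.empty(P)
    w2 = np.empty(P)
    excluded = np.zeros(P, dtype=bool)
    for p in range(P):
        th = theta[p + 1]
        J1 = float(th @ omega1 @ th)
        J2 = float(th @ omega2 @ th)
        if J1 <= 0.0:
            w1[p] = np.inf
            w2[p] = np.inf
            excluded[p] = True
            continue
        w1[p] = 1.0 / np.sqrt(J1)
        w2[p] = 1.0 / np.sqrt(max(J2, eps * J1))
    return AdaptiveWeights(w1=w1, w2=w2, excluded=excluded)


class AdaptiveFit(NamedTuple):
    fit: FitResult
    cv: Optional[CVResult]
    weights: AdaptiveWeights


def fit_adaptive(
    dataset: RegionDataset,
    basis: NaturalCubicBasis,
    matrices: PenaltyMatrices,
    weights: AdaptiveWeights,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    L: int = DEFAULT_PATH_LENGTH,
    tau: Optional[float] = None,
    n_folds: int = 5,
    seed: int = 0,
    rule: str = "one_se",
    config: Optional[SolverConfig] = None,
    folds: Optional[np.ndarray] = None,
) -> AdaptiveFit:
    """Full reweighted pipeline: per-group metrics, path, CV, selection."""
    if np.all(weights.excluded):
        logger.warning("all covariates excluded by adaptive weights; "
                       "returning the intercept-only model")
        intercept = fit_intercept_only(dataset, basis)
        fit = FitResult(
            coefs=intercept,
            eta=intercept.to_eta(
                compose_penalty(matrices, 0.0, 0.0, dataset.P)
            ),
            objective_trace=np.asarray(
                [neg2_loglik_from_pi(
                    dataset.meth, dataset.total,
                    predict_pi(intercept, dataset, basis))]
            ),
            selected=[],
            lam=np.inf,
            alpha=0.0,
            weights=weights.as_pairs(),
            converged=True,
            n_iter=0,
        )
        return AdaptiveFit(fit=fit, cv=None, weights=weights)

    cv = cross_validate(
        dataset, basis, matrices, alpha_grid=alpha_grid,
        weights=weights.as_pairs(), L=L, tau=tau, n_folds=n_folds,
        seed=seed, config=config, folds=folds,
    )
    a, l = cv.chosen_index(rule)
    fit = cv.full_paths[a].fits[l]
    return AdaptiveFit(fit=fit, cv=cv, weights=weights)


class BasisDimensions(NamedTuple):
    intercept: int
    snp: int


def basis_dimension_rule(n_cpgs: int) -> BasisDimensions:
    """Spline dimensions for a real region of ``n_cpgs`` sites.

    The SNP-effect dimension is min(10, n_cpgs // 10), clamped below at 4
    (the natural cubic minimum); the intercept dimension is fixed at 10.
    """
    if n_cpgs < 1:
        raise ValueError("need at least one CpG")
    k_snp = max(4, min(10, n_cpgs // 10))
    return BasisDimensions(intercept=10, snp=k_snp)
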