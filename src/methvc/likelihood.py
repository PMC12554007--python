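"""Design assembly and the binomial likelihood in both coordinate systems.

The model is a binomial varying-coefficient regression: for record
(i, j) with genotype dosages ``Z_i``,

    logit pi_ij = beta_0(t_ij) + sum_p beta_p(t_ij) Z_ip,
    Y_ij ~ Binomial(X_ij, pi_ij),

with each ``beta_p`` expanded in a K-dimensional spline basis.  The design
block for covariate p has entries ``b_k(t_ij) * Z_ip`` (``Z_i0 = 1`` for
the intercept).  For the group-penalized solver, each penalized block is
transformed by the inverse triangular factor of its penalty metric,
``X~_p = X_p L_p^{-1}``, so that the penalty becomes a plain Euclidean
group norm on ``eta_p = L_p theta_p``.

The objective throughout is the twice-negative log-likelihood

    l(theta) = -2 sum_ij [ Y_ij log pi_ij + (X_ij - Y_ij) log(1 - pi_ij) ],

with the constant binomial coefficient term omitted.  Probabilities are
clipped to [1e-10, 1 - 1e-10] before taking logs so the objective stays
finite during line searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .basis import NaturalCubicBasis, PenaltyOperator
from .data import RegionDataset

PI_CLIP = 1e-10


@dataclass
class DesignMatrices:
    """Stacked design in original (B, Z) and reparameterized coordinates.

    ``Xt`` is the M x (P+1)K matrix [X~_0 | X~_1 | ... | X~_P] with the
    intercept block untransformed and each penalized block multiplied by
    its group's ``L_p^{-1}``.  ``frozen`` marks groups pinned at zero: those
    excluded by infinite adaptive weights or with an all-zero design block
    (monomorphic SNPs).
    """

    B: np.ndarray           # (M, K) raw basis rows
    Z: np.ndarray           # (N, P) dosages
    sample_idx: np.ndarray  # (M,)
    Xt: np.ndarray          # (M, (P+1)K) transformed stacked design
    basis: NaturalCubicBasis
    penalty: PenaltyOperator
    frozen: np.ndarray      # (P,) bool

    @property
    def K(self) -> int:
        return self.B.shape[1]

    @property
    def P(self) -> int:
        return self.Z.shape[1]

    @property
    def n_coef(self) -> int:
        return (self.P + 1) * self.K

    def group_slice(self, p: int) -> slice:
        """Columns of group p (p = 0 is the intercept)."""
        return slice(p * self.K, (p + 1) * self.K)

    def original_block(self, p: int) -> np.ndarray:
        """Untransformed design block X_p (entries b_k(t_ij) Z_ip)."""
        if p == 0:
            return self.B
        return self.B * self.Z[self.sample_idx, p - 1][:, None]


def assemble_design(
    dataset: RegionDataset,
    basis: NaturalCubicBasis,
    penalty: PenaltyOperator,
) -> DesignMatrices:
    """Build the stacked (transformed) design for a dataset and penalty."""
    if penalty.P != dataset.P:
        raise ValueError(
            f"penalty composed for {penalty.P} covariates, dataset has {dataset.P}"
        )
    B = basis.evaluate(dataset.positions)
    K = basis.K
    P = dataset.P
    Zrec = dataset.genotypes[dataset.sample_idx]  # (M, P)
    Xt = np.empty((dataset.M, (P + 1) * K))
    Xt[:, :K] = B
    frozen = np.zeros(P, dtype=bool)
    for p in range(P):
        block = B * Zrec[:, p][:, None]
        if not np.any(block):
            frozen[p] = True
            Xt[:, (p + 1) * K:(p + 2) * K] = 0.0
            continue
        if penalty.excluded[p]:
            frozen[p] = True
        Xt[:, (p + 1) * K:(p + 2) * K] = block @ penalty.Linv[p]
    return DesignMatrices(
        B=B,
        Z=dataset.genotypes,
        sample_idx=dataset.sample_idx,
        Xt=Xt,
        basis=basis,
        penalty=penalty,
        frozen=frozen,
    )


@dataclass
class CoefficientSet:
    """Basis coefficients as a (P+1) x K matrix (row 0 = intercept).

    ``eta`` is the reparameterized form ``eta_p = L_p theta_p`` for the
    penalized groups (the intercept is shared between the two systems).
    """

    theta: np.ndarray
    basis: NaturalCubicBasis

    @classmethod
    def zeros(cls, P: int, basis: NaturalCubicBasis) -> "CoefficientSet":
        return cls(theta=np.zeros((P + 1, basis.K)), basis=basis)

    def to_eta(self, penalty: PenaltyOperator) -> np.ndarray:
        """Flat eta vector of length (P+1)K."""
        K = self.basis.K
        eta = np.empty(self.theta.size)
        eta[:K] = self.theta[0]
        for p in range(penalty.P):
            eta[(p + 1) * K:(p + 2) * K] = penalty.L[p] @ self.theta[p + 1]
        return eta

    @classmethod
    def from_eta(
        cls, eta: np.ndarray, basis: NaturalCubicBasis, penalty: PenaltyOperator
    ) -> "CoefficientSet":
        K = basis.K
        P = penalty.P
        theta = np.empty((P + 1, K))
        theta[0] = eta[:K]
        for p in range(P):
            eta_p = eta[(p + 1) * K:(p + 2) * K]
            if np.any(eta_p):
                theta[p + 1] = penalty.Linv[p] @ eta_p
            else:
                theta[p + 1] = 0.0  # exact zeros survive the back-transform
        return cls(theta=theta, basis=basis)


def clip_pi(pi: np.ndarray) -> np.ndarray:
    return np.clip(pi, PI_CLIP, 1.0 - PI_CLIP)


def neg2_loglik_from_pi(meth, total, pi) -> float:
    pi = clip_pi(pi)
    return float(-2.0 * np.sum(meth * np.log(pi) + (total - meth) * np.log1p(-pi)))


def neg2_loglik_eta(eta: np.ndarray, design: DesignMatrices, dataset: RegionDataset) -> float:
    """l(eta) on the transformed design (equals l(theta) at eta = L theta)."""
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite coefficients")
    pi = expit(design.Xt @ eta)
    return neg2_loglik_from_pi(dataset.meth, dataset.total, pi)


def gradient_eta(eta: np.ndarray, design: DesignMatrices, dataset: RegionDataset) -> np.ndarray:
    """Gradient of l in the reparameterized coordinates:
    -2 X~' (Y - X pi)."""
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite coefficients")
    pi = expit(design.Xt @ eta)
    resid = dataset.meth - dataset.total * pi
    return -2.0 * (design.Xt.T @ resid)


def neg2_loglik(coefs: CoefficientSet, design: DesignMatrices, dataset: RegionDataset) -> float:
    """l(theta) evaluated through the original design blocks."""
    return neg2_loglik_from_pi(
        dataset.meth, dataset.total, predict_pi(coefs, dataset, design.basis)
    )


def gradient(
    coefs: CoefficientSet,
    design: DesignMatrices,
    dataset: RegionDataset,
    space: str = "original",
) -> np.ndarray:
    """Gradient of l, stacked per block, in the requested coordinates."""
    pi = expit(_linear_predictor(coefs.theta, dataset, design.B))
    resid = dataset.meth - dataset.total * pi
    K = design.K
    g = np.empty((design.P + 1) * K)
    for p in range(design.P + 1):
        gp = -2.0 * (design.original_block(p).T @ resid)
        if space == "reparameterized" and p >= 1:
            gp = design.penalty.Linv[p - 1].T @ gp
        g[p * K:(p + 1) * K] = gp
    return g


def _linear_predictor(theta: np.ndarray, dataset: RegionDataset, B: np.ndarray) -> np.ndarray:
    curves_at_records = B @ theta.T  # (M, P+1)
    Zrec = dataset.genotypes[dataset.sample_idx]
    return curves_at_records[:, 0] + np.einsum(
        "mp,mp->m", curves_at_records[:, 1:], Zrec
    )


def predict_pi(
    coefs: CoefficientSet, dataset: RegionDataset, basis: NaturalCubicBasis
) -> np.ndarray:
    """Fitted methylation probabilities at the dataset's records."""
    B = basis.evaluate(dataset.positions)
    return expit(_linear_predictor(coefs.theta, dataset, B))


def coefficient_functions(
    coefs: CoefficientSet, basis: NaturalCubicBasis, grid
) -> np.ndarray:
    """Evaluate every beta_p on a grid of raw positions; rows are covariates."""
    B = basis.evaluate(grid)
    return coefs.theta @ B.T  # (P+1, n_grid)
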