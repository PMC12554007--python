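"""Natural cubic spline bases and the penalty matrices built on them.

Coefficient functions ``beta_p(t)`` are expanded in a natural cubic spline
basis of dimension ``K`` over genomic positions rescaled to the unit
interval.  The composite penalty on each function combines its squared L2
norm ``J1 = theta' Omega1 theta`` and its curvature energy
``J2 = theta' Omega2 theta``, where::

    Omega1[k, k'] = int b_k(t) b_k'(t) dt
    Omega2[k, k'] = M^2 int b_k''(t) b_k''(t) dt

with ``M`` the total number of methylation records; the ``M^2`` factor puts
the two terms on comparable scales so that a single mixing weight
``alpha`` in ``H_alpha = (1 - alpha) Omega1 + alpha Omega2`` can trade them
off across datasets.

The basis is the cardinal interpolation basis: ``b_k`` is the natural cubic
spline taking value 1 at knot k and 0 at every other knot.  Any natural
cubic basis spanning the same space gives the same fitted functions; only
the raw coefficient values are basis dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline
from scipy.linalg import LinAlgError, cholesky


class NaturalCubicBasis:
    """Cardinal natural cubic spline basis over a rescaled genomic region.

    Parameters
    ----------
    knots : array-like
        Strictly increasing knot locations on the rescaled axis [0, 1].
    raw_range : (float, float)
        Original bp minimum and maximum used for the affine rescaling.
    """

    def __init__(self, knots: Sequence[float], raw_range: tuple[float, float]):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or knots.size < 4:
            raise ValueError("need at least 4 knots for a natural cubic basis")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if knots[0] < -1e-12 or knots[-1] > 1 + 1e-12:
            raise ValueError("rescaled knots must lie in [0, 1]")
        self.knots = knots
        self.raw_range = (float(raw_range[0]), float(raw_range[1]))
        # b_k interpolates the k-th unit vector at the knots; natural
        # boundary conditions give zero second derivative at both ends.
        self._spline = CubicSpline(knots, np.eye(self.K), bc_type="natural")

    @property
    def K(self) -> int:
        return self.knots.size

    def rescale(self, positions) -> np.ndarray:
        """Map raw bp positions affinely onto [0, 1], clamping to the range."""
        positions = np.asarray(positions, dtype=float)
        if not np.all(np.isfinite(positions)):
            raise ValueError("non-finite positions")
        lo, hi = self.raw_range
        t = (positions - lo) / (hi - lo)
        return np.clip(t, 0.0, 1.0)

    def evaluate_rescaled(self, t, deriv: int = 0) -> np.ndarray:
        """Evaluate the K basis functions (or a derivative) at rescaled t."""
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            return np.empty((0, self.K))
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite evaluation points")
        if deriv == 0:
            return self._spline(t)
        return self._spline(t, nu=deriv)

    def evaluate(self, positions, deriv: int = 0) -> np.ndarray:
        """Evaluate at raw bp positions (rescaled and clamped internally)."""
        return self.evaluate_rescaled(self.rescale(positions), deriv=deriv)


def build_basis(positions, K: int) -> NaturalCubicBasis:
    """Construct the basis for a region from its observed CpG positions.

    Knots are placed at equally spaced quantiles of the distinct rescaled
    positions, with the first and last knots at the region boundaries.
    """
    if K < 4:
        raise ValueError("basis dimension K must be at least 4")
    positions = np.asarray(positions, dtype=float)
    distinct = np.unique(positions)
    if distinct.size < K:
        raise ValueError(
            f"region has only {distinct.size} distinct positions; "
            f"cannot place {K} knots"
        )
    lo, hi = distinct[0], distinct[-1]
    t = (distinct - lo) / (hi - lo)
    knots = np.quantile(t, np.linspace(0.0, 1.0, K))
    knots[0], knots[-1] = 0.0, 1.0
    # quantiles of nearly coincident positions can collide; nudge apart
    for k in range(1, K):
        if knots[k] <= knots[k - 1]:
            knots[k] = np.nextafter(knots[k - 1], 1.0)
    return NaturalCubicBasis(knots, (lo, hi))


def _gauss_nodes_per_interval(knots: np.ndarray, n_nodes: int):
    """Gauss-Legendre nodes/weights mapped onto each inter-knot interval."""
    x, w = leggauss(n_nodes)
    a, b = knots[:-1], knots[1:]
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def compute_omega1(basis: NaturalCubicBasis, n_nodes: int = 4) -> np.ndarray:
    """Gram matrix of the basis functions, integrated exactly over [0, 1].

    The integrand is piecewise polynomial of degree 6, so Gauss-Legendre
    with >= 4 nodes per inter-knot interval is exact.
    """
    if n_nodes < 4:
        raise ValueError("need >= 4 Gauss nodes for exactness")
    nodes, weights = _gauss_nodes_per_interval(basis.knots, n_nodes)
    B = basis.evaluate_rescaled(nodes)
    omega = (B * weights[:, None]).T @ B
    return 0.5 * (omega + omega.T)


def compute_omega2(basis: NaturalCubicBasis, M: int, n_nodes: int = 2) -> np.ndarray:
    """Curvature penalty matrix ``M^2 * int b'' b''`` (piecewise quadratic
    integrand; >= 2 Gauss nodes per interval are exact)."""
    if M < 1:
        raise ValueError("total record count M must be >= 1")
    if n_nodes < 2:
        raise ValueError("need >= 2 Gauss nodes for exactness")
    nodes, weights = _gauss_nodes_per_interval(basis.knots, n_nodes)
    B2 = basis.evaluate_rescaled(nodes, deriv=2)
    omega = (B2 * weights[:, None]).T @ B2
    return float(M) ** 2 * 0.5 * (omega + omega.T)


@dataclass(frozen=True)
class PenaltyMatrices:
    """The two K x K penalty matrices and the record count they are scaled by.

    The model pipeline integrates over genomic distance (bp): with the
    basis built on the rescaled unit axis and W the region width in bp,
    the change of variables gives ``int beta^2 dt = W * theta' Omega1u
    theta`` and ``int (beta'')^2 dt = W^-3 * theta' Omega2u theta``.  On
    this measure the ``M^2`` factor in ``J2`` puts the size and curvature
    terms on comparable scales for regions of typical width, which is
    what makes a mixing grid over alpha meaningful; on the bare unit axis
    ``J2`` would dwarf ``J1`` by many orders of magnitude and any
    alpha > 0 would collapse into a near-pure curvature penalty.
    """

    omega1: np.ndarray
    omega2_unscaled: np.ndarray  # int b'' b'' without the M^2 factor
    M: int

    @property
    def omega2(self) -> np.ndarray:
        return float(self.M) ** 2 * self.omega2_unscaled

    @classmethod
    def from_basis(cls, basis: NaturalCubicBasis, M: int) -> "PenaltyMatrices":
        """Matrices on the genomic (bp) integration axis."""
        lo, hi = basis.raw_range
        width = hi - lo
        return cls(
            omega1=width * compute_omega1(basis),
            omega2_unscaled=compute_omega2(basis, 1) / width**3,
            M=int(M),
        )

    @classmethod
    def from_basis_unit_axis(cls, basis: NaturalCubicBasis, M: int) -> "PenaltyMatrices":
        """Matrices with integrals taken on the rescaled [0, 1] axis."""
        return cls(
            omega1=compute_omega1(basis),
            omega2_unscaled=compute_omega2(basis, 1),
            M=int(M),
        )

    def to_tsv(self, omega1_path, omega2_path) -> None:
        """Export both matrices as TSV for inspection."""
        np.savetxt(omega1_path, self.omega1, delimiter="\t")
        np.savetxt(omega2_path, self.omega2, delimiter="\t")


def _chol_upper(H: np.ndarray) -> np.ndarray:
    """Upper-triangular factor L with L'L = H, jittered only on failure."""
    try:
        return cholesky(H, lower=False)
    except LinAlgError:
        jitter = 1e-10 * np.trace(H) / H.shape[0]
        return cholesky(H + jitter * np.eye(H.shape[0]), lower=False)


@dataclass
class PenaltyOperator:
    """Per-covariate penalty metric ``H_p`` and its triangular factor.

    For the ordinary penalty all covariates share
    ``H_alpha = (1 - alpha) Omega1 + alpha Omega2``; adaptive weights
    ``(w1p, w2p)`` change the metric per covariate:
    ``H_p = w1p (1 - alpha) Omega1 + w2p alpha Omega2``.  Covariates with an
    infinite weight are excluded from the model (their coefficients are
    pinned at zero).  The identity override replaces every ``H_p`` by the
    identity matrix, which turns the penalty into a plain group LASSO on
    the basis coefficients.
    """

    alpha: float
    lam: float
    H: list[np.ndarray]
    L: list[np.ndarray]
    Linv: list[np.ndarray]
    weights: np.ndarray  # (P, 2) pairs (w1p, w2p); inf marks exclusion
    excluded: np.ndarray  # (P,) bool
    identity: bool = False

    @property
    def P(self) -> int:
        return len(self.H)

    def penalty_value(self, theta_groups: np.ndarray) -> float:
        """lambda * sum_p sqrt(theta_p' H_p theta_p) over penalized groups."""
        total = 0.0
        for p in range(self.P):
            if self.excluded[p]:
                continue
            th = theta_groups[p]
            total += np.sqrt(max(th @ self.H[p] @ th, 0.0))
        return self.lam * total


def compose_penalty(
    matrices: PenaltyMatrices,
    alpha: float,
    lam: float,
    P: int,
    weights=None,
    identity: bool = False,
) -> PenaltyOperator:
    """Build the per-covariate penalty metrics for P penalized covariates.

    ``alpha = 1`` is rejected: a pure-curvature penalty does not penalize
    constant or linear components and can lead to non-unique, unbounded
    solutions.
    """
    if not (0.0 <= alpha < 1.0):
        raise ValueError(
            "alpha must lie in [0, 1): alpha = 1 leaves linear functions "
            "unpenalized and can lead to non-unique, unbounded solutions"
        )
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if weights is None:
        weights = np.ones((P, 2))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (P, 2):
        raise ValueError(f"weights must have shape ({P}, 2)")
    if np.any(weights <= 0):
        raise ValueError("penalty weights must be positive (or infinite)")

    excluded = ~np.all(np.isfinite(weights), axis=1)
    K = matrices.omega1.shape[0]
    H_list: list[np.ndarray] = []
    L_list: list[np.ndarray] = []
    Linv_list: list[np.ndarray] = []

    if identity:
        eye = np.eye(K)
        for p in range(P):
            H_list.append(eye)
            L_list.append(eye)
            Linv_list.append(eye)
    else:
        omega2 = matrices.omega2
        shared = None
        for p in range(P):
            if excluded[p]:
                # never entered into the fit; keep a placeholder metric
                H_list.append(np.eye(K))
                L_list.append(np.eye(K))
                Linv_list.append(np.eye(K))
                continue
            w1, w2 = weights[p]
            if w1 == 1.0 and w2 == 1.0:
                if shared is None:
                    H = (1.0 - alpha) * matrices.omega1 + alpha * omega2
                    L = _chol_upper(H)
                    shared = (H, L, np.linalg.inv(L))
                H, L, Linv = shared
            else:
                H = w1 * (1.0 - alpha) * matrices.omega1 + w2 * alpha * omega2
                L = _chol_upper(H)
                Linv = np.linalg.inv(L)
            H_list.append(H)
            L_list.append(L)
            Linv_list.append(Linv)

    return PenaltyOperator(
        alpha=float(alpha),
        lam=float(lam),
        H=H_list,
        L=L_list,
        Linv=Linv_list,
        weights=weights,
        excluded=excluded,
        identity=identity,
    )
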