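"""Synthetic regional methylation data with known position-varying SNP effects.

The generator emulates a targeted bisulfite-sequencing region: a fixed set
of irregularly spaced CpG sites, an N x P genotype matrix with
block-diagonal linkage disequilibrium, and binomial read counts drawn from
the varying-coefficient model

    logit pi_ij = beta_0(t_ij) + sum_p beta_p(t_ij) Z_ip,
    X_ij ~ Poisson(depth_mean) truncated to >= 1,
    Y_ij ~ Binomial(X_ij, pi_ij).

Genotypes come from thresholded-Gaussian haplotypes: within each LD block
the latent Gaussians are exchangeable with correlation ``rho``, an allele
is carried when the latent value exceeds the (1 - maf) normal quantile,
and the dosage is the sum of two independent haplotypes, giving valid
{0, 1, 2} genotypes with tunable within-block correlation.

Only ``n_causal`` of the P effect curves are nonzero.  The smooth shape
library (constant, linear, quadratic-like, bimodal) mirrors the varied
smooth effects of the study design's first example; the nonsmooth shape
(piecewise constant with sharp interior jumps) stresses the smoothness
assumption.  When ``rho > 0`` the causal SNPs are co-located in a single
LD block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .data import RegionDataset

REGION_START = 100_000
REGION_WIDTH = 3_000

SMOOTH_SHAPES = ("constant", "linear", "quadratic_like", "bimodal")


def _shape_constant(t):
    return np.ones_like(t)


def _shape_linear(t):
    return 2.0 * t - 1.0


def _shape_quadratic(t):
    # centered parabola spanning [-1, 1]
    return 1.0 - 8.0 * (t - 0.5) ** 2 / 2.0


def _shape_bimodal(t):
    return (
        np.exp(-0.5 * ((t - 0.3) / 0.08) ** 2)
        + 0.8 * np.exp(-0.5 * ((t - 0.75) / 0.10) ** 2)
    )


def _shape_nonsmooth(t):
    out = np.zeros_like(t)
    out[(t >= 0.15) & (t < 0.40)] = 1.0
    out[(t >= 0.60) & (t < 0.72)] = -1.0
    return out


SHAPE_LIBRARY: dict[str, Callable] = {
    "constant": _shape_constant,
    "linear": _shape_linear,
    "quadratic_like": _shape_quadratic,
    "bimodal": _shape_bimodal,
    "nonsmooth_sharp": _shape_nonsmooth,
}


def baseline_curve(t: np.ndarray) -> np.ndarray:
    """Smooth baseline methylation curve beta_0 on the rescaled axis."""
    return 0.5 * np.cos(2.0 * np.pi * t) - 0.3


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for one synthetic region."""

    n_samples: int = 50
    n_snps: int = 100
    n_causal: int = 5
    rho: float = 0.0
    block_size: int = 20
    n_cpgs: int = 123
    shapes: tuple[str, ...] = SMOOTH_SHAPES + ("bimodal",)
    effect_scale: float = 1.0
    maf: float = 0.3
    depth_mean: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        unknown = [s for s in self.shapes if s not in SHAPE_LIBRARY]
        if unknown:
            raise ValueError(f"unknown effect shapes {unknown}")

    @classmethod
    def example_smooth(cls, **overrides) -> "SimulationScenario":
        """Smooth effects of varied shapes spanning the full region."""
        return cls(**overrides)

    @classmethod
    def example_nonsmooth(cls, **overrides) -> "SimulationScenario":
        """Sharp piecewise-constant effects violating the smoothness model."""
        overrides.setdefault("shapes", ("nonsmooth_sharp",) * 5)
        return cls(**overrides)


# presets named after the two study designs
example1 = SimulationScenario.example_smooth
example2 = SimulationScenario.example_nonsmooth


@dataclass
class SimulatedRegion:
    """A dataset bundled with its generating truth."""

    dataset: RegionDataset
    cpg_positions: np.ndarray   # (n_cpgs,) raw bp
    true_beta: np.ndarray       # (P+1, n_cpgs) including the baseline row 0
    true_pi: np.ndarray         # (M,) per-record success probabilities
    causal_set: np.ndarray      # 1-based causal SNP indices
    scenario: SimulationScenario


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    rho: float,
    block_size: int = 20,
    maf: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Dosage matrix from thresholded-Gaussian haplotype pairs."""
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cut = norm.ppf(1.0 - maf)
    n_blocks = int(np.ceil(n_snps / block_size))
    Z = np.zeros((n_samples, n_snps))
    for _ in range(2):  # two independent haplotypes
        latent = np.empty((n_samples, n_snps))
        for b in range(n_blocks):
            lo, hi = b * block_size, min((b + 1) * block_size, n_snps)
            shared = rng.standard_normal((n_samples, 1))
            noise = rng.standard_normal((n_samples, hi - lo))
            latent[:, lo:hi] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
        Z += latent > cut
    return Z


def true_effect_functions(scenario: SimulationScenario, t: np.ndarray) -> np.ndarray:
    """The P effect curves on the rescaled grid; only n_causal are nonzero.

    Causal shapes cycle through the scenario's shape list; when rho > 0 the
    causal SNPs occupy the first LD block, otherwise the first indices.
    """
    curves = np.zeros((scenario.n_snps, t.size))
    for j, idx in enumerate(causal_indices(scenario)):
        shape = scenario.shapes[j % len(scenario.shapes)]
        curves[idx - 1] = scenario.effect_scale * SHAPE_LIBRARY[shape](t)
    return curves


def causal_indices(scenario: SimulationScenario) -> np.ndarray:
    """1-based indices of the causal SNPs (within one block when rho > 0)."""
    if scenario.rho > 0 and scenario.n_causal > scenario.block_size:
        raise ValueError("causal SNPs must fit within one LD block when rho > 0")
    return np.arange(1, scenario.n_causal + 1)


def simulate_methylation(
    Z: np.ndarray,
    beta: np.ndarray,
    positions: np.ndarray,
    depth_mean: float = 30.0,
    seed: int | np.random.Generator = 0,
) -> tuple[RegionDataset, np.ndarray]:
    """Binomial read counts at every (sample, CpG) pair from given curves.

    ``beta`` is (P+1, n_cpgs) with the baseline in row 0, evaluated at
    ``positions``.  Returns the dataset and the true per-record
    probabilities.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_samples = Z.shape[0]
    n_cpgs = positions.size
    logit = beta[0][None, :] + Z @ beta[1:]  # (N, n_cpgs)
    pi = expit(logit)
    depth = rng.poisson(depth_mean, size=(n_samples, n_cpgs))
    while np.any(depth == 0):  # truncate the depth distribution at 1
        zero = depth == 0
        depth[zero] = rng.poisson(depth_mean, size=int(zero.sum()))
    meth = rng.binomial(depth, pi)
    dataset = RegionDataset(
        sample_idx=np.repeat(np.arange(n_samples), n_cpgs),
        positions=np.tile(positions, n_samples),
        meth=meth.ravel(),
        total=depth.ravel(),
        genotypes=Z,
    )
    return dataset, pi.ravel()


def cpg_positions(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    """Irregularly spaced CpG coordinates across a ~3 kb region."""
    offsets = np.sort(
        rng.choice(REGION_WIDTH, size=scenario.n_cpgs, replace=False)
    )
    return (REGION_START + offsets).astype(float)


def generate_scenario(scenario: SimulationScenario) -> SimulatedRegion:
    """Genotypes, truth curves and read counts for one scenario; the whole
    construction is deterministic given the scenario seed."""
    rng = np.random.default_rng(scenario.seed)
    positions = cpg_positions(scenario, rng)
    t = (positions - positions[0]) / (positions[-1] - positions[0])
    effect = true_effect_functions(scenario, t)
    beta = np.vstack([baseline_curve(t)[None, :], effect])
    Z = simulate_genotypes(
        scenario.n_samples, scenario.n_snps, scenario.rho,
        scenario.block_size, scenario.maf, rng,
    )
    dataset, true_pi = simulate_methylation(
        Z, beta, positions, scenario.depth_mean, rng
    )
    return SimulatedRegion(
        dataset=dataset,
        cpg_positions=positions,
        true_beta=beta,
        true_pi=true_pi,
        causal_set=causal_indices(scenario),
        scenario=scenario,
    )
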