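"""Scaled-down replication of the simulation study's comparisons.

Runs repeated synthetic regions under the smooth-effect design (123 CpG
sites, N samples, P candidate SNPs of which 5 carry smooth effects of
varied shapes, independent genotypes) and compares the three penalty
families — SSP (sparsity + smoothness), SSP0 (sparsity only, alpha = 0)
and group LASSO (identity metric) — on integrated estimation error,
held-out prediction error, and selection counts, together with the 1-SE
selection rule and the adaptive reweighting variant of SSP.

Problem sizes are configurable; the defaults (R = 4 runs, P = 100, a
15-value lambda path, alpha grid {0, 0.5, 0.99}, 3-fold CV) are chosen so
the full study runs in minutes on one CPU while preserving the design's
high-dimensional structure.  A smaller companion study refits the three
families with a K = 30 basis to probe sensitivity to the basis dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .basis import PenaltyMatrices, build_basis
from .data import RegionDataset
from .estimators import SparseSmoothVCMCV
from .likelihood import coefficient_functions, predict_pi
from .metrics import estimation_metrics, prediction_metrics, selection_metrics
from .simulate import SimulationScenario, generate_scenario
from .solver import SolverConfig
from .tuning import adaptive_weights, cross_validate, fit_adaptive, make_folds

STUDY_ALPHA_GRID = (0.0, 0.5, 0.99)


@dataclass
class StudyConfig:
    n_runs: int = 4
    n_samples: int = 50
    n_snps: int = 100
    n_causal: int = 5
    n_cpgs: int = 123
    effect_scale: float = 1.0
    rho: float = 0.0
    K: int = 10
    alpha_grid: Sequence[float] = STUDY_ALPHA_GRID
    n_lambda: int = 15
    tau: float = 0.02
    n_folds: int = 3
    n_test_samples: int = 50
    tol: float = 1e-5
    seed: int = 1


@dataclass
class StudyResult:
    """Per-method aggregates over the study's runs."""

    imse_total: dict[str, float]
    ibias2_total: dict[str, float]
    ivar_total: dict[str, float]
    tp_mean: dict[str, float]
    fp_mean: dict[str, float]
    deviance_error: dict[str, float]
    cor_raw: dict[str, float]
    rmse: dict[str, float]
    n_runs: int
    config: StudyConfig


def _fit_variants(dataset, basis, matrices, config, run_seed):
    """One run's fits: SSP (min & 1-SE & adaptive), SSP0, gLASSO.

    Returns {variant: (coef_curves_fn, selected)} with curves evaluated
    lazily on any grid, sharing the CV surfaces across the selection-rule
    variants so min/1-SE/adaptive differ only in the rule or reweighting.
    """
    solver = SolverConfig(tol=config.tol)
    folds = make_folds(dataset, config.n_folds, run_seed)
    out = {}

    cv_ssp = cross_validate(
        dataset, basis, matrices, alpha_grid=config.alpha_grid,
        L=config.n_lambda, tau=config.tau, n_folds=config.n_folds,
        seed=run_seed, config=solver, folds=folds,
    )
    for rule, name in (("min", "ssp"), ("one_se", "ssp_1se")):
        a, l = cv_ssp.chosen_index(rule)
        out[name] = cv_ssp.full_paths[a].fits[l]

    w = adaptive_weights(out["ssp"], matrices)
    adp = fit_adaptive(
        dataset, basis, matrices, w, alpha_grid=config.alpha_grid,
        L=config.n_lambda, tau=config.tau, n_folds=config.n_folds,
        seed=run_seed, rule="min", config=solver, folds=folds,
    )
    out["ssp_adaptive"] = adp.fit

    for name, kwargs in (
        ("ssp0", dict(alpha_grid=(0.0,))),
        ("glasso", dict(alpha_grid=(0.0,), identity=True)),
    ):
        cv = cross_validate(
            dataset, basis, matrices, L=config.n_lambda, tau=config.tau,
            n_folds=config.n_folds, seed=run_seed, config=solver,
            folds=folds, **kwargs,
        )
        a, l = cv.chosen_index("min")
        out[name] = cv.full_paths[a].fits[l]
    return out


def run_study(config: Optional[StudyConfig] = None) -> StudyResult:
    """Run the full comparison and aggregate the evaluation measures."""
    config = config or StudyConfig()
    variants = ("ssp", "ssp_1se", "ssp_adaptive", "ssp0", "glasso")
    curves: dict[str, list[np.ndarray]] = {v: [] for v in variants}
    tp: dict[str, list[int]] = {v: [] for v in variants}
    fp: dict[str, list[int]] = {v: [] for v in variants}
    dev: dict[str, list[float]] = {v: [] for v in variants}
    craw: dict[str, list[float]] = {v: [] for v in variants}
    rmse: dict[str, list[float]] = {v: [] for v in variants}
    truth = None

    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.n_runs)
    seeds = (seeds % (2**31 - 1)).astype(int)
    for r in range(config.n_runs):
        scenario = SimulationScenario(
            n_samples=config.n_samples, n_snps=config.n_snps,
            n_causal=config.n_causal, rho=config.rho,
            n_cpgs=config.n_cpgs, effect_scale=config.effect_scale,
            seed=int(seeds[2 * r]),
        )
        sim = generate_scenario(scenario)
        test_sim = generate_scenario(
            SimulationScenario(
                n_samples=config.n_test_samples, n_snps=config.n_snps,
                n_causal=config.n_causal, rho=config.rho,
                n_cpgs=config.n_cpgs, effect_scale=config.effect_scale,
                seed=int(seeds[2 * r + 1]),
            )
        )
        ds = sim.dataset
        basis = build_basis(ds.positions, config.K)
        matrices = PenaltyMatrices.from_basis(basis, ds.M)
        truth = sim.true_beta[1:]  # effect curves on the CpG grid

        fits = _fit_variants(ds, basis, matrices, config, int(seeds[2 * r]))
        for name, fit in fits.items():
            est = coefficient_functions(fit.coefs, basis, sim.cpg_positions)[1:]
            curves[name].append(est)
            tpv, fpv = selection_metrics(
                fit.selected, sim.causal_set, P=config.n_snps
            )
            tp[name].append(tpv)
            fp[name].append(fpv)
            # the test region shares the truth curves but not the CpG grid
            # realization; predict at the test records through the basis
            pred = predict_pi(fit.coefs, test_sim.dataset, basis)
            rep = prediction_metrics(pred, test_sim.dataset, test_sim.true_pi)
            dev[name].append(rep.deviance_error)
            craw[name].append(rep.cor_raw if rep.cor_raw is not None else np.nan)
            rmse[name].append(rep.rmse)

    def total(reports, key):
        return {
            v: float(getattr(estimation_metrics(np.stack(curves[v]), truth), key).sum())
            for v in variants
        }

    return StudyResult(
        imse_total=total(curves, "imse"),
        ibias2_total=total(curves, "ibias2"),
        ivar_total=total(curves, "ivar"),
        tp_mean={v: float(np.mean(tp[v])) for v in variants},
        fp_mean={v: float(np.mean(fp[v])) for v in variants},
        deviance_error={v: float(np.mean(dev[v])) for v in variants},
        cor_raw={v: float(np.nanmean(craw[v])) for v in variants},
        rmse={v: float(np.mean(rmse[v])) for v in variants},
        n_runs=config.n_runs,
        config=config,
    )


def run_basis_dimension_study(
    config: Optional[StudyConfig] = None,
    dims: Sequence[int] = (10, 30),
) -> dict[int, dict[str, float]]:
    """Total IMSE of SSP / SSP0 / gLASSO at two basis dimensions.

    Probes the claim that the smoothness penalty makes the fit insensitive
    to an over-rich basis while sparsity-only penalties degrade.
    """
    config = config or StudyConfig(n_runs=2)
    solver = SolverConfig(tol=config.tol)
    methods = ("ssp", "ssp0", "glasso")
    curves = {K: {m: [] for m in methods} for K in dims}
    truth = None
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    seeds = (seeds % (2**31 - 1)).astype(int)
    for r in range(config.n_runs):
        scenario = SimulationScenario(
            n_samples=config.n_samples, n_snps=config.n_snps,
            n_causal=config.n_causal, rho=config.rho,
            n_cpgs=config.n_cpgs, effect_scale=config.effect_scale,
            seed=int(seeds[r]),
        )
        sim = generate_scenario(scenario)
        ds = sim.dataset
        truth = sim.true_beta[1:]
        for K in dims:
            basis = build_basis(ds.positions, K)
            matrices = PenaltyMatrices.from_basis(basis, ds.M)
            folds = make_folds(ds, config.n_folds, int(seeds[r]))
            for m in methods:
                kwargs = (
                    dict(alpha_grid=config.alpha_grid) if m == "ssp"
                    else dict(alpha_grid=(0.0,), identity=(m == "glasso"))
                )
                cv = cross_validate(
                    ds, basis, matrices, L=config.n_lambda, tau=config.tau,
                    n_folds=config.n_folds, seed=int(seeds[r]),
                    config=solver, folds=folds, **kwargs,
                )
                a, l = cv.chosen_index("min")
                fit = cv.full_paths[a].fits[l]
                est = coefficient_functions(fit.coefs, basis, sim.cpg_positions)[1:]
                curves[K][m].append(est)
    return {
        K: {
            m: float(estimation_metrics(np.stack(curves[K][m]), truth).imse.sum())
            for m in methods
        }
        for K in dims
    }
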