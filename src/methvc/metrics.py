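"""Monte-Carlo evaluation measures for estimation, prediction, selection.

Estimation accuracy of a coefficient-function estimator is summarized over
R simulation runs and a position grid by the integrated (summed over grid
points) squared bias, variance, and mean squared error:

    IBIAS^2 = sum_t [Ehat(t) - beta(t)]^2
    IVAR    = sum_t (1/R) sum_r [betahat_r(t) - Ehat(t)]^2
    IMSE    = sum_t (1/R) sum_r [betahat_r(t) - beta(t)]^2

with ``Ehat(t)`` the across-run mean estimate; IMSE = IBIAS^2 + IVAR holds
as an algebraic identity.  Prediction on held-out records uses the
deviance error (mean excess of -2 log-likelihood of predictions over that
of the true probabilities), the RMSE on the variance-stabilized arcsine
scale ``h(pi) = arcsin(2 pi - 1)``, and Pearson correlations between the
predicted and observed proportions on the raw (CorRaw) and transformed
(CorTrans) scales.  Selection accuracy counts true and false positives of
the selected SNP set against the causal set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import RegionDataset
from .likelihood import neg2_loglik_from_pi


@dataclass
class EstimationReport:
    """Per-covariate integrated error measures over R runs."""

    ibias2: np.ndarray
    ivar: np.ndarray
    imse: np.ndarray
    n_runs: int

    @property
    def totals(self) -> dict:
        return {
            "ibias2": float(self.ibias2.sum()),
            "ivar": float(self.ivar.sum()),
            "imse": float(self.imse.sum()),
        }


def estimation_metrics(estimates: np.ndarray, truth: np.ndarray) -> EstimationReport:
    """Integrated bias/variance/MSE of curve estimates across runs.

    Parameters
    ----------
    estimates : (R, C, T) or (R, T) array
        Estimated curves for R runs, C covariates, T grid points.
    truth : (C, T) or (T,) array
        True curves on the same grid.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.ndim == 2:
        estimates = estimates[:, None, :]
        truth = truth[None, :]
    if estimates.shape[1:] != truth.shape:
        raise ValueError(
            f"grid mismatch: estimates {estimates.shape[1:]}, truth {truth.shape}"
        )
    mean_est = estimates.mean(axis=0)
    ibias2 = ((mean_est - truth) ** 2).sum(axis=1)
    ivar = ((estimates - mean_est[None]) ** 2).mean(axis=0).sum(axis=1)
    imse = ((estimates - truth[None]) ** 2).mean(axis=0).sum(axis=1)
    return EstimationReport(
        ibias2=ibias2, ivar=ivar, imse=imse, n_runs=estimates.shape[0]
    )


def arcsine(pi: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform h(pi) = arcsin(2 pi - 1)."""
    return np.arcsin(np.clip(2.0 * np.asarray(pi, dtype=float) - 1.0, -1.0, 1.0))


@dataclass
class PredictionReport:
    deviance_error: Optional[float]
    rmse: float
    cor_raw: Optional[float]
    cor_trans: Optional[float]

    def as_dict(self) -> dict:
        return {
            "deviance_error": self.deviance_error,
            "rmse": self.rmse,
            "cor_raw": self.cor_raw,
            "cor_trans": self.cor_trans,
        }


def _pearson(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    if np.std(a) == 0 or np.std(b) == 0:
        return None  # undefined for degenerate inputs; flagged as missing
    return float(np.corrcoef(a, b)[0, 1])


def prediction_metrics(
    pred_pi: np.ndarray,
    dataset: RegionDataset,
    true_pi: Optional[np.ndarray] = None,
) -> PredictionReport:
    """Held-out prediction measures for per-record probability estimates."""
    pred_pi = np.asarray(pred_pi, dtype=float)
    y, n = dataset.meth, dataset.total
    M = dataset.M
    deviance_error = None
    if true_pi is not None:
        deviance_error = (
            neg2_loglik_from_pi(y, n, pred_pi) - neg2_loglik_from_pi(y, n, true_pi)
        ) / M
    obs = y / n
    h_pred = arcsine(pred_pi)
    h_obs = arcsine(obs)
    rmse = float(np.sqrt(np.mean((h_pred - h_obs) ** 2)))
    return PredictionReport(
        deviance_error=deviance_error,
        rmse=rmse,
        cor_raw=_pearson(pred_pi, obs),
        cor_trans=_pearson(h_pred, h_obs),
    )


def selection_metrics(
    selected: Sequence[int], causal: Sequence[int], P: Optional[int] = None
) -> tuple[int, int]:
    """True/false positive counts of a selected SNP set (1-based indices)."""
    selected = set(int(s) for s in selected)
    causal = set(int(c) for c in causal)
    if P is not None:
        bad = [i for i in selected | causal if not (1 <= i <= P)]
        if bad:
            raise ValueError(f"indices outside 1..{P}: {sorted(bad)}")
    tp = len(selected & causal)
    fp = len(selected - causal)
    return tp, fp
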