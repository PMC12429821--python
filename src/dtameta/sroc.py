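"""Summary ROC curve, AUC and per-study display statistics.

The summary curve is the conditional-expectation line of the fitted
bivariate normal mapped to ROC space:

    Se(f) = expit( mu_se + rho * (sigma_se / sigma_sp) * (logit(1 - f) - mu_sp) )

where f is the false-positive rate.  The AUC integrates Se(f) over the full
f in [0, 1] by the trapezoid rule, with the f = 0 and f = 1 endpoints filled
in by the curve's limits (restricting to the observed FPR range is a common
alternative; printed AUC values are therefore treated as soft checks only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .model import BivariateParams
from .records import ContingencyTable

DEFAULT_GRID_POINTS = 1999


def default_grid(points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Uniform FPR grid strictly inside (0, 1): 0.0005 ... 0.9995 by default."""
    return np.linspace(0.5 / (points + 1) * 2, 1 - 0.5 / (points + 1) * 2, points)


@dataclass(frozen=True)
class SROCResult:
    fpr: np.ndarray
    sensitivity: np.ndarray
    params: BivariateParams


@dataclass(frozen=True)
class StudyDisplayStat:
    """Point estimates with exact binomial 95% intervals, for crosshair plots."""

    sensitivity: float
    se_lo: float
    se_hi: float
    specificity: float
    sp_lo: float
    sp_hi: float


def _expit(x):
    from scipy.special import expit

    return expit(x)


def _logit(p):
    return np.log(p) - np.log1p(-p)


def sroc_curve(
    params: BivariateParams, grid: np.ndarray | None = None
) -> SROCResult:
    """Evaluate the summary curve on an FPR grid strictly inside (0, 1)."""
    f = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any((f <= 0.0) | (f >= 1.0)):
        raise ValueError("grid points must lie strictly inside (0, 1)")
    if np.any(np.diff(f) <= 0):
        raise ValueError("grid must be strictly increasing")
    se = _curve_values(f, params.mu_se, params.mu_sp,
                       params.sigma_se, params.sigma_sp, params.rho)
    return SROCResult(fpr=f, sensitivity=se, params=params)


def _curve_values(f, mu_se, mu_sp, sigma_se, sigma_sp, rho):
    return _expit(mu_se + rho * (sigma_se / sigma_sp) * (_logit(1.0 - f) - mu_sp))


def _endpoint_limits(mu_se, sigma_se, sigma_sp, rho):
    """Curve limits at f -> 0+ and f -> 1- (sign of rho decides saturation)."""
    flat = _expit(mu_se)
    at0 = np.where(rho < 0, 0.0, np.where(rho > 0, 1.0, flat))
    at1 = np.where(rho < 0, 1.0, np.where(rho > 0, 0.0, flat))
    return at0, at1


def sroc_auc(curve: SROCResult) -> float:
    """Trapezoidal AUC over f in [0, 1], endpoints filled by the curve limits."""
    f, se = curve.fpr, curve.sensitivity
    if np.any(np.diff(f) <= 0):
        raise ValueError("grid must be strictly increasing")
    p = curve.params
    at0, at1 = _endpoint_limits(p.mu_se, p.sigma_se, p.sigma_sp, np.asarray(p.rho))
    ff = np.concatenate(([0.0], f, [1.0]))
    ss = np.concatenate(([float(at0)], se, [float(at1)]))
    return float(np.trapezoid(ss, ff))


def auc_from_draws(mu_se, mu_sp, sigma_se, sigma_sp, rho,
                   grid: np.ndarray | None = None) -> np.ndarray:
    """Draw-wise AUC for posterior parameter draws (vectorized trapezoid)."""
    f = default_grid() if grid is None else np.asarray(grid, dtype=float)
    mu_se, mu_sp, sigma_se, sigma_sp, rho = map(
        np.atleast_1d, (mu_se, mu_sp, sigma_se, sigma_sp, rho)
    )
    se = _curve_values(
        f[None, :], mu_se[:, None], mu_sp[:, None],
        sigma_se[:, None], sigma_sp[:, None], rho[:, None],
    )
    at0, at1 = _endpoint_limits(mu_se, sigma_se, sigma_sp, rho)
    ff = np.concatenate(([0.0], f, [1.0]))
    ss = np.concatenate([at0[:, None], se, at1[:, None]], axis=1)
    return np.trapezoid(ss, ff, axis=1)


def clopper_pearson(successes: int, trials: int, level: float = 0.95):
    """Exact binomial confidence interval from beta quantiles."""
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError("need 0 <= successes <= trials, trials >= 1")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(
        beta_dist.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


def study_intervals(
    data: Sequence[ContingencyTable], level: float = 0.95
) -> list[StudyDisplayStat]:
    """Per-study sensitivity/specificity with exact 95% intervals."""
    out = []
    for t in data:
        se_lo, se_hi = clopper_pearson(t.tp, t.n_diseased, level)
        sp_lo, sp_hi = clopper_pearson(t.tn, t.n_healthy, level)
        out.append(
            StudyDisplayStat(
                sensitivity=t.tp / t.n_diseased, se_lo=se_lo, se_hi=se_hi,
                specificity=t.tn / t.n_healthy, sp_lo=sp_lo, sp_hi=sp_hi,
            )
        )
    return out
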