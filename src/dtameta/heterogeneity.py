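"""Per-margin heterogeneity, funnel-plot coordinates and Egger-type asymmetry.

Heterogeneity is quantified on logit-transformed proportions (or the log
diagnostic odds ratio) with fixed-effect inverse-variance weights: Cochran's
Q, and I^2 = max(0, (Q - df) / Q).  Publication bias is examined with the
classical Egger precision regression per margin and a generalized bivariate
combination: both margins stacked into one regression whose two intercepts
are tested jointly with a 2-df Wald statistic under a study-clustered
covariance.
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .records import ContingencyTable

MARGINS = ("sensitivity", "specificity", "lnDOR")


@dataclass(frozen=True)
class MarginEffects:
    """Per-study effect sizes and within-study variances for one margin."""

    margin: str
    theta: np.ndarray
    variance: np.ndarray

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        v = np.asarray(self.variance, dtype=float)
        if th.shape != v.shape or th.ndim != 1:
            raise ValueError("theta and variance must be equal-length 1-D arrays")
        if np.any(v <= 0):
            raise ValueError("within-study variances must be positive")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "variance", v)

    @property
    def k(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    i2_pct: float
    p: float


@dataclass(frozen=True)
class EggerMargin:
    intercept: float
    se: float
    t: float
    p: float
    slope: float


@dataclass(frozen=True)
class EggerResult:
    sensitivity: EggerMargin
    specificity: EggerMargin
    combined_chi2: float
    combined_df: int
    combined_p: float


@dataclass(frozen=True)
class FunnelData:
    theta: np.ndarray
    se: np.ndarray          # sqrt of within-study variance (y axis, inverted)
    center: float           # fixed-effect pooled estimate
    bound_se: np.ndarray    # grid of precision values for the funnel wedge
    lower: np.ndarray
    upper: np.ndarray


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    """0.5 added to all four cells only when any cell is zero."""
    cells = (t.tp, t.fp, t.tn, t.fn)
    if min(cells) == 0:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def logit_effects(
    data: Sequence[ContingencyTable], margin: str = "sensitivity"
) -> MarginEffects:
    """Logit (or lnDOR) effects with delta-method within-study variances."""
    if margin not in MARGINS:
        raise ValueError(f"margin must be one of {MARGINS}")
    theta = np.empty(len(data))
    var = np.empty(len(data))
    for i, t in enumerate(data):
        tp, fp, tn, fn = _corrected_cells(t)
        if margin == "sensitivity":
            theta[i] = np.log(tp / fn)
            var[i] = 1.0 / tp + 1.0 / fn
        elif margin == "specificity":
            theta[i] = np.log(tn / fp)
            var[i] = 1.0 / tn + 1.0 / fp
        else:
            theta[i] = np.log(tp * tn / (fp * fn))
            var[i] = 1.0 / tp + 1.0 / fp + 1.0 / tn + 1.0 / fn
    return MarginEffects(margin=margin, theta=theta, variance=var)


def q_and_i2(effects: MarginEffects) -> HeterogeneityResult:
    """Cochran's Q with fixed-effect weights and the derived I^2 (percent)."""
    if effects.k < 2:
        raise ValueError("heterogeneity needs at least two studies")
    w = 1.0 / effects.variance
    theta_bar = float(np.sum(w * effects.theta) / np.sum(w))
    q = float(np.sum(w * (effects.theta - theta_bar) ** 2))
    df = effects.k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, i2_pct=i2, p=p)


def fixed_effect_mean(effects: MarginEffects) -> float:
    w = 1.0 / effects.variance
    return float(np.sum(w * effects.theta) / np.sum(w))


def funnel_points(effects: MarginEffects, n_bound: int = 50) -> FunnelData:
    """Study coordinates plus the 95% pseudo-confidence funnel wedge."""
    se = np.sqrt(effects.variance)
    center = fixed_effect_mean(effects)
    grid = np.linspace(0.0, se.max() * 1.05, n_bound)
    return FunnelData(
        theta=effects.theta.copy(),
        se=se,
        center=center,
        bound_se=grid,
        lower=center - 1.96 * grid,
        upper=center + 1.96 * grid,
    )


def _egger_margin(effects: MarginEffects) -> EggerMargin:
    """Classical Egger regression: theta/sqrt(v) on 1/sqrt(v), OLS."""
    prec = 1.0 / np.sqrt(effects.variance)
    snd = effects.theta * prec
    X = sm.add_constant(prec)
    res = sm.OLS(snd, X).fit()
    icpt, se = float(res.params[0]), float(res.bse[0])
    if se == 0.0:  # exact fit (noiseless effects): no evidence of asymmetry
        tval, p = 0.0, 1.0
    else:
        tval = icpt / se
        p = 2.0 * float(stats.t.sf(abs(tval), effects.k - 2))
    return EggerMargin(intercept=icpt, se=se, t=tval, p=p, slope=float(res.params[1]))


def egger_test(
    se_effects: MarginEffects, sp_effects: MarginEffects
) -> EggerResult:
    """Per-margin Egger intercept tests plus a 2-df bivariate combination.

    The combination stacks both margins' precision regressions into one
    design (separate intercept and slope per margin) and tests the two
    intercepts jointly with a Wald chi-square under a covariance clustered
    on study — each study contributes one observation to each margin, and
    within-study sensitivity/specificity errors may be correlated.
    """
    if se_effects.k != sp_effects.k:
        raise ValueError("margins must cover the same studies")
    k = se_effects.k
    if k < 3:
        raise ValueError("Egger regression needs at least three studies")

    m_se = _egger_margin(se_effects)
    m_sp = _egger_margin(sp_effects)

    rows = []
    y = []
    groups = []
    for m_idx, eff in enumerate((se_effects, sp_effects)):
        prec = 1.0 / np.sqrt(eff.variance)
        snd = eff.theta * prec
        for i in range(k):
            ind = [0.0, 0.0, 0.0, 0.0]
            ind[2 * m_idx] = 1.0          # margin intercept
            ind[2 * m_idx + 1] = prec[i]  # margin slope
            rows.append(ind)
            y.append(snd[i])
            groups.append(i)
    X = np.asarray(rows)
    res = sm.OLS(np.asarray(y), X).fit(
        cov_type="cluster", cov_kwds={"groups": np.asarray(groups)}
    )
    # Joint test that both intercepts (columns 0 and 2) are zero.  The
    # cluster covariance supplies the cross-margin dependence, but its
    # diagonal is downward-biased at meta-analysis-sized k (few clusters,
    # high-leverage precision values), which makes the plain cluster Wald
    # liberal; the per-margin classical variances (k - 2 df each) replace
    # the diagonal, and the statistic is referred to F(2, k - 2).
    vc = np.asarray(res.cov_params())
    r_cross = vc[0, 2] / math.sqrt(vc[0, 0] * vc[2, 2]) if vc[0, 0] * vc[2, 2] > 0 else 0.0
    # degenerate (duplicated-margin) input would make the 2x2 covariance singular
    r_cross = float(np.clip(r_cross, -0.9999, 0.9999))
    b = np.array([m_se.intercept, m_sp.intercept])
    d = np.array([m_se.se, m_sp.se])
    if np.any(d == 0.0):
        chi2, p = 0.0, 1.0
    else:
        cov = np.array(
            [[d[0] ** 2, r_cross * d[0] * d[1]],
             [r_cross * d[0] * d[1], d[1] ** 2]]
        )
        chi2 = float(b @ np.linalg.solve(cov, b))
        p = float(stats.f.sf(chi2 / 2.0, 2, k - 2))
    return EggerResult(
        sensitivity=m_se,
        specificity=m_sp,
        combined_chi2=chi2,
        combined_df=2,
        combined_p=p,
    )
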