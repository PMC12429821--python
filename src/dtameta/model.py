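"""Bayesian bivariate binomial-normal model for diagnostic test accuracy.

Within study *i*, true positives and true negatives are binomial,

    tp_i ~ Bin(tp_i + fn_i, expit(mu_se + phi_se_i))
    tn_i ~ Bin(tn_i + fp_i, expit(mu_sp + phi_sp_i))

and the study-level logit deviations (phi_se_i, phi_sp_i) follow a bivariate
normal with standard deviations (sigma_se, sigma_sp) and correlation rho.
Priors: diffuse normals on the two fixed effects, penalized-complexity
(exponential) priors on both random-effect SDs with P(sigma > u) = alpha,
and a diffuse normal on the Fisher-z transformed correlation.

The posterior is explored with an adaptive random-walk Metropolis-within-
Gibbs sampler over four blocks — the fixed-effect pair, the log-SD pair, the
Fisher-z correlation, and all study-level effect pairs at once (conditionally
independent across studies, so they are updated in a single vectorized
step).  All chains run simultaneously as a leading array axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .records import ContingencyTable

logger = logging.getLogger(__name__)

#: bound on the Fisher-z correlation state (|rho| < 1 - 1e-10); see sampler
Z_MAX = 12.0
#: hyperparameter block sweeps per iteration
HYPER_REPEATS = 5
#: SD of the fixed independence proposal on the Fisher-z correlation
Z_IND_SD = 2.0

__all__ = [
    "BivariateParams",
    "PriorSpec",
    "LatentEffects",
    "PosteriorSummary",
    "QuantitySummary",
    "pc_prior_logdensity",
    "pc_rate",
    "log_joint",
    "fit_mcmc",
    "summarize_posterior",
]


@dataclass(frozen=True)
class BivariateParams:
    """Logit-scale means, SDs and correlation of the bivariate random effect."""

    mu_se: float
    mu_sp: float
    sigma_se: float
    sigma_sp: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma_se <= 0 or self.sigma_sp <= 0:
            raise ValueError("sigma_se and sigma_sp must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def pooled_sensitivity(self) -> float:
        return float(_expit(self.mu_se))

    @property
    def pooled_specificity(self) -> float:
        return float(_expit(self.mu_sp))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior.

    ``mu_sd`` and ``z_sd`` make the customary "large variance" normals
    concrete (flat over the plausible logit / Fisher-z range while keeping
    the posterior proper); ``pc_u``/``pc_alpha`` are the PC-prior threshold
    and tail probability for each random-effect SD.
    """

    mu_sd: float = 10.0
    pc_u: float = 3.0
    pc_alpha: float = 0.05
    z_sd: float = 5.0

    def __post_init__(self) -> None:
        if min(self.mu_sd, self.pc_u, self.z_sd) <= 0:
            raise ValueError("mu_sd, pc_u and z_sd must be positive")
        if not 0.0 < self.pc_alpha < 1.0:
            raise ValueError("pc_alpha must lie in (0, 1)")


@dataclass(frozen=True)
class LatentEffects:
    """Per-study logit-scale deviations from the fixed effects, shape (k, 2)."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.phi, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("phi must have shape (k, 2)")
        object.__setattr__(self, "phi", arr)


@dataclass(frozen=True)
class QuantitySummary:
    median: float
    mean: float
    lo: float
    hi: float


@dataclass
class PosteriorSummary:
    """Posterior medians/means and equal-tailed 95% intervals per quantity."""

    quantities: dict[str, QuantitySummary]
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    acceptance: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    draws: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, key: str) -> QuantitySummary:
        return self.quantities[key]


def _expit(x):
    from scipy.special import expit

    return expit(x)


def _softplus(x):
    return np.logaddexp(0.0, x)


def pc_rate(pc_u: float, pc_alpha: float) -> float:
    """Rate of the PC (exponential) prior with tail P(sigma > u) = alpha."""
    return -math.log(pc_alpha) / pc_u


def pc_prior_logdensity(sigma, pc_u: float = 3.0, pc_alpha: float = 0.05):
    """Log density of the PC prior on a Gaussian random-effect SD.

    The penalized-complexity prior shrinking toward the no-heterogeneity base
    model is exponential in sigma; non-positive sigma gets ``-inf`` so the
    sampler rejects such states rather than raising.
    """
    lam = pc_rate(pc_u, pc_alpha)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(sigma > 0, math.log(lam) - lam * sigma, -np.inf)
    return out if out.ndim else float(out)


def _data_arrays(data: Sequence[ContingencyTable]):
    tp = np.array([t.tp for t in data], dtype=float)
    fn = np.array([t.fn for t in data], dtype=float)
    tn = np.array([t.tn for t in data], dtype=float)
    fp = np.array([t.fp for t in data], dtype=float)
    return tp, fn, tn, fp


def _binom_loglik(counts_pos, counts_neg, x, *, with_const: bool):
    """log Bin(counts_pos | counts_pos + counts_neg, expit(x)), vectorized."""
    ll = -counts_pos * _softplus(-x) - counts_neg * _softplus(x)
    if with_const:
        n = counts_pos + counts_neg
        ll = ll + gammaln(n + 1) - gammaln(counts_pos + 1) - gammaln(counts_neg + 1)
    return ll


def _mvn_pair_logpdf(phi_se, phi_sp, sigma_se, sigma_sp, rho):
    """Bivariate normal log density of centered effect pairs (broadcasting)."""
    a = phi_se / sigma_se
    b = phi_sp / sigma_sp
    one_m_r2 = 1.0 - rho**2
    quad = (a**2 - 2.0 * rho * a * b + b**2) / one_m_r2
    return (
        -math.log(2.0 * math.pi)
        - np.log(sigma_se)
        - np.log(sigma_sp)
        - 0.5 * np.log(one_m_r2)
        - 0.5 * quad
    )


def log_joint(
    params: BivariateParams,
    effects: LatentEffects,
    data: Sequence[ContingencyTable],
    prior: PriorSpec = PriorSpec(),
) -> float:
    """Joint log density of data, latent effects and parameters.

    Includes the binomial coefficients, the bivariate normal of the latent
    effects, the normal priors on the fixed effects, the PC priors on both
    SDs, and the normal prior on z = atanh(rho) together with the Jacobian
    of the z -> rho change of variable.  Out-of-support states give ``-inf``.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    phi = effects.phi
    if phi.shape[0] != len(data):
        raise ValueError("one effect pair required per study")
    if params.sigma_se <= 0 or params.sigma_sp <= 0 or abs(params.rho) >= 1.0:
        return -np.inf

    tp, fn, tn, fp = _data_arrays(data)
    ll = float(
        np.sum(_binom_loglik(tp, fn, params.mu_se + phi[:, 0], with_const=True))
        + np.sum(_binom_loglik(tn, fp, params.mu_sp + phi[:, 1], with_const=True))
    )
    ll += float(
        np.sum(
            _mvn_pair_logpdf(
                phi[:, 0], phi[:, 1], params.sigma_se, params.sigma_sp, params.rho
            )
        )
    )
    # normal priors on fixed effects
    for mu in (params.mu_se, params.mu_sp):
        ll += -0.5 * math.log(2.0 * math.pi) - math.log(prior.mu_sd) \
            - 0.5 * (mu / prior.mu_sd) ** 2
    # PC priors on the SDs
    ll += float(pc_prior_logdensity(params.sigma_se, prior.pc_u, prior.pc_alpha))
    ll += float(pc_prior_logdensity(params.sigma_sp, prior.pc_u, prior.pc_alpha))
    # normal prior on z = atanh(rho), plus |dz/drho| = 1/(1 - rho^2)
    z = math.atanh(params.rho)
    ll += -0.5 * math.log(2.0 * math.pi) - math.log(prior.z_sd) \
        - 0.5 * (z / prior.z_sd) ** 2
    ll += -math.log(1.0 - params.rho**2)
    return ll


# --------------------------------------------------------------------------
# sampler


def _init_state(tp, fn, tn, fp, chains, rng, fix_rho):
    """Empirical initialization with per-chain jitter."""
    k = tp.shape[0]
    logit_se = np.log((tp + 0.5) / (fn + 0.5))
    logit_sp = np.log((tn + 0.5) / (fp + 0.5))
    mu0 = np.array([logit_se.mean(), logit_sp.mean()])
    resid = np.stack([logit_se - mu0[0], logit_sp - mu0[1]], axis=-1)
    sd0 = np.maximum(resid.std(axis=0), 0.2)

    mu = mu0[None, :] + 0.3 * rng.standard_normal((chains, 2))
    ls = np.log(sd0)[None, :] + 0.3 * rng.standard_normal((chains, 2))
    if fix_rho is None:
        z = np.clip(0.2 * rng.standard_normal(chains), -2.0, 2.0)
    else:
        z = np.full(chains, math.atanh(fix_rho))
    phi = 0.5 * resid[None, :, :] + 0.1 * rng.standard_normal((chains, k, 2))
    return mu, ls, z, phi


def fit_mcmc(
    data: Sequence[ContingencyTable],
    prior: PriorSpec = PriorSpec(),
    *,
    chains: int = 4,
    iters_per_chain: int = 10_000,
    seed: int = 0,
    burn_frac: float = 0.5,
    rhat_threshold: float = 1.05,
    fix_rho: float | None = None,
    prior_only: bool = False,
    auc_draws: int = 2000,
) -> PosteriorSummary:
    """Fit the bivariate model by adaptive Metropolis-within-Gibbs MCMC.

    The default budget is 4 chains x 10,000 iterations (40,000 total), the
    first half of each chain discarded as burn-in.  Proposal scales adapt
    during burn-in toward a 20-50% acceptance rate and are then frozen.
    With a single study the correlation is not identifiable and must be
    fixed (``fix_rho``); ``prior_only`` drops the binomial likelihood so the
    sampler draws from the prior (used to verify the PC-prior tail).

    A result whose split-chain R-hat exceeds ``rhat_threshold`` on any
    hyperparameter is returned flagged (``converged=False``) with its
    diagnostics, never silently.
    """
    if len(data) == 0:
        raise ValueError("data must be non-empty")
    if len(data) == 1 and fix_rho is None:
        raise ValueError(
            "a single study cannot identify the correlation; pass fix_rho=0.0"
        )
    if fix_rho is not None and not -1.0 < fix_rho < 1.0:
        raise ValueError("fix_rho must lie strictly inside (-1, 1)")

    tp, fn, tn, fp = _data_arrays(data)
    k = len(data)
    C = chains
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    mu, ls, z, phi = _init_state(tp, fn, tn, fp, C, rng, fix_rho)
    lam = pc_rate(prior.pc_u, prior.pc_alpha)
    burn = int(round(burn_frac * iters_per_chain))
    keep = iters_per_chain - burn
    lik = 0.0 if prior_only else 1.0

    # proposal log-scales, adapted per chain (phi: per chain x study)
    ls_mu = np.full(C, math.log(0.2))
    ls_ls = np.full(C, math.log(0.3))
    ls_z = np.full(C, math.log(0.5))
    ls_phi = np.full((C, k), math.log(0.5))
    ls_nc = np.full(C, math.log(0.2))
    ls_mu_nc = np.full(C, math.log(0.3))
    target = 0.30

    def binom_terms(mu_arr, phi_arr):
        """Per-study log-likelihood pair, shape (C, k) each margin."""
        x_se = mu_arr[:, 0:1] + phi_arr[:, :, 0]
        x_sp = mu_arr[:, 1:2] + phi_arr[:, :, 1]
        return (
            _binom_loglik(tp, fn, x_se, with_const=False),
            _binom_loglik(tn, fp, x_sp, with_const=False),
        )

    def mvn_terms(phi_arr, ls_arr, z_arr):
        # 1 - rho^2 computed as sech^2(z): stable however far z wanders
        sig = np.exp(ls_arr)
        rho = np.tanh(z_arr)[:, None]
        az = np.abs(z_arr)[:, None]
        log_1m_r2 = -2.0 * (az + np.log1p(np.exp(-2.0 * az)) - math.log(2.0))
        a = phi_arr[:, :, 0] / sig[:, 0:1]
        b = phi_arr[:, :, 1] / sig[:, 1:2]
        quad = (a**2 - 2.0 * rho * a * b + b**2) * np.exp(-log_1m_r2)
        return (
            -math.log(2.0 * math.pi)
            - np.log(sig[:, 0:1])
            - np.log(sig[:, 1:2])
            - 0.5 * log_1m_r2
            - 0.5 * quad
        )

    ll_se, ll_sp = binom_terms(mu, phi)
    mvn = mvn_terms(phi, ls, z)

    store = {
        name: np.empty((C, keep))
        for name in ("mu_se", "mu_sp", "sigma_se", "sigma_sp", "rho")
    }
    acc_count = {"mu": 0.0, "sigma": 0.0, "z": 0.0, "phi": 0.0, "nc": 0.0, "mu_nc": 0.0}
    acc_total = {"mu": 0, "sigma": 0, "z": 0, "phi": 0, "nc": 0, "mu_nc": 0}

    for it in range(iters_per_chain):
        adapting = it < burn
        gamma = (it + 1) ** -0.6 if adapting else 0.0

        # --- block 1: all study effects at once (independent given hyperparams)
        prop = phi + np.exp(ls_phi)[:, :, None] * rng.standard_normal((C, k, 2))
        p_se, p_sp = binom_terms(mu, prop)
        p_mvn = mvn_terms(prop, ls, z)
        delta = lik * (p_se - ll_se + p_sp - ll_sp) + p_mvn - mvn
        accept = np.log(rng.random((C, k))) < delta
        phi = np.where(accept[:, :, None], prop, phi)
        ll_se = np.where(accept, p_se, ll_se)
        ll_sp = np.where(accept, p_sp, ll_sp)
        mvn = np.where(accept, p_mvn, mvn)
        if adapting:
            ls_phi += gamma * (accept.astype(float) - target)
        else:
            acc_count["phi"] += accept.mean()
            acc_total["phi"] += 1

        # --- block 2: fixed-effect pair
        prop_mu = mu + np.exp(ls_mu)[:, None] * rng.standard_normal((C, 2))
        p_se, p_sp = binom_terms(prop_mu, phi)
        delta = lik * (p_se - ll_se + p_sp - ll_sp).sum(axis=1)
        delta += -0.5 * ((prop_mu**2).sum(axis=1) - (mu**2).sum(axis=1)) / prior.mu_sd**2
        accept = np.log(rng.random(C)) < delta
        mu = np.where(accept[:, None], prop_mu, mu)
        ll_se = np.where(accept[:, None], p_se, ll_se)
        ll_sp = np.where(accept[:, None], p_sp, ll_sp)
        if adapting:
            ls_mu += gamma * (accept.astype(float) - target)
        else:
            acc_count["mu"] += accept.mean()
            acc_total["mu"] += 1

        # --- block 2b: interweaved location move.  Holds the per-study sums
        # mu + phi_i fixed (likelihood cancels) so mu can travel even when the
        # data pin each study's total logit tightly.
        prop_mu = mu + np.exp(ls_mu_nc)[:, None] * rng.standard_normal((C, 2))
        shift = (mu - prop_mu)[:, None, :]
        prop_phi = phi + shift
        p_mvn = mvn_terms(prop_phi, ls, z)
        delta = (p_mvn - mvn).sum(axis=1)
        delta += -0.5 * ((prop_mu**2).sum(axis=1) - (mu**2).sum(axis=1)) / prior.mu_sd**2
        accept = np.log(rng.random(C)) < delta
        mu = np.where(accept[:, None], prop_mu, mu)
        phi = np.where(accept[:, None, None], prop_phi, phi)
        mvn = np.where(accept[:, None], p_mvn, mvn)
        if adapting:
            ls_mu_nc += gamma * (accept.astype(float) - target)
        else:
            acc_count["mu_nc"] += accept.mean()
            acc_total["mu_nc"] += 1

        # the hyperparameter blocks are cheap relative to the effect updates,
        # so they run several times per sweep to speed sigma/rho mixing
        for _ in range(HYPER_REPEATS):
            # --- block 3: log-SD pair (PC prior + log-scale Jacobian)
            prop_ls = ls + np.exp(ls_ls)[:, None] * rng.standard_normal((C, 2))
            p_mvn = mvn_terms(phi, prop_ls, z)
            delta = (p_mvn - mvn).sum(axis=1)
            delta += (-lam * np.exp(prop_ls) + prop_ls + lam * np.exp(ls) - ls).sum(axis=1)
            accept = np.log(rng.random(C)) < delta
            ls = np.where(accept[:, None], prop_ls, ls)
            mvn = np.where(accept[:, None], p_mvn, mvn)
            if adapting:
                ls_ls += gamma * (accept.astype(float) - target)
            else:
                acc_count["sigma"] += accept.mean()
                acc_total["sigma"] += 1

            # --- block 4: Fisher-z correlation (|z| bounded: past Z_MAX the
            # correlation is saturated to within 1e-10 and the posterior
            # carries no mass, so the bound only avoids numerical overflow)
            if fix_rho is None:
                prop_z = z + np.exp(ls_z) * rng.standard_normal(C)
                p_mvn = mvn_terms(phi, ls, prop_z)
                delta = (p_mvn - mvn).sum(axis=1)
                delta += -0.5 * (prop_z**2 - z**2) / prior.z_sd**2
                delta = np.where(np.abs(prop_z) > Z_MAX, -np.inf, delta)
                accept = np.log(rng.random(C)) < delta
                z = np.where(accept, prop_z, z)
                mvn = np.where(accept[:, None], p_mvn, mvn)
                if adapting:
                    ls_z += gamma * (accept.astype(float) - target)
                else:
                    acc_count["z"] += accept.mean()
                    acc_total["z"] += 1

            # --- block 4b: non-centered independence proposal on z.  The
            # random walk can linger with |rho| ~ 1 and near-collinear
            # effects; holding the whitened effects fixed and drawing z from
            # a fixed wide proposal jumps such states back to the bulk in one
            # move (the MH ratio includes the proposal densities).
            if fix_rho is None:
                sig = np.exp(ls)
                rho = np.tanh(z)
                root = 1.0 / np.cosh(z)
                u1 = phi[:, :, 0] / sig[:, 0:1]
                u2 = (phi[:, :, 1] / sig[:, 1:2] - rho[:, None] * u1) / root[:, None]
                prop_z = Z_IND_SD * rng.standard_normal(C)
                p_rho = np.tanh(prop_z)
                p_root = 1.0 / np.cosh(prop_z)
                prop_phi = phi.copy()
                prop_phi[:, :, 1] = sig[:, 1:2] * (
                    p_rho[:, None] * u1 + p_root[:, None] * u2
                )
                p_sp = _binom_loglik(tn, fp, mu[:, 1:2] + prop_phi[:, :, 1],
                                     with_const=False)
                delta = lik * (p_sp - ll_sp).sum(axis=1)
                delta += -0.5 * (prop_z**2 - z**2) / prior.z_sd**2
                delta += 0.5 * (prop_z**2 - z**2) / Z_IND_SD**2  # q(z)/q(z')
                accept = np.log(rng.random(C)) < delta
                z = np.where(accept, prop_z, z)
                phi = np.where(accept[:, None, None], prop_phi, phi)
                ll_sp = np.where(accept[:, None], p_sp, ll_sp)
                mvn = mvn_terms(phi, ls, z)

            # --- block 5: interweaved non-centered update of (log-SDs, z).
            # The centered blocks above leave phi fixed, which couples the
            # hyperparameters to the current effects (the "funnel") and can
            # stall sigma/rho mixing; this step holds the whitened effects
            # u = L^{-1} phi fixed instead, rescaling phi with the proposal.
            sig = np.exp(ls)
            rho = np.tanh(z)
            root = 1.0 / np.cosh(z)  # sqrt(1 - rho^2), exact and positive
            u1 = phi[:, :, 0] / sig[:, 0:1]
            u2 = (phi[:, :, 1] / sig[:, 1:2] - rho[:, None] * u1) / root[:, None]
            step = np.exp(ls_nc)[:, None] * rng.standard_normal((C, 3))
            if fix_rho is not None:
                step[:, 2] = 0.0
            prop_ls = ls + step[:, :2]
            prop_z = z + step[:, 2]
            p_sig = np.exp(prop_ls)
            p_rho = np.tanh(prop_z)
            p_root = 1.0 / np.cosh(prop_z)
            prop_phi = np.empty_like(phi)
            prop_phi[:, :, 0] = p_sig[:, 0:1] * u1
            prop_phi[:, :, 1] = p_sig[:, 1:2] * (
                p_rho[:, None] * u1 + p_root[:, None] * u2
            )
            p_se, p_sp = binom_terms(mu, prop_phi)
            delta = lik * (p_se - ll_se + p_sp - ll_sp).sum(axis=1)
            delta += (-lam * p_sig + prop_ls + lam * np.exp(ls) - ls).sum(axis=1)
            if fix_rho is None:
                delta += -0.5 * (prop_z**2 - z**2) / prior.z_sd**2
            delta = np.where(np.abs(prop_z) > Z_MAX, -np.inf, delta)
            accept = np.log(rng.random(C)) < delta
            phi = np.where(accept[:, None, None], prop_phi, phi)
            ls = np.where(accept[:, None], prop_ls, ls)
            z = np.where(accept, prop_z, z)
            ll_se = np.where(accept[:, None], p_se, ll_se)
            ll_sp = np.where(accept[:, None], p_sp, ll_sp)
            mvn = mvn_terms(phi, ls, z)
            if adapting:
                ls_nc += gamma * (accept.astype(float) - target)
            else:
                acc_count["nc"] += accept.mean()
                acc_total["nc"] += 1

        if not adapting:
            j = it - burn
            store["mu_se"][:, j] = mu[:, 0]
            store["mu_sp"][:, j] = mu[:, 1]
            store["sigma_se"][:, j] = np.exp(ls[:, 0])
            store["sigma_sp"][:, j] = np.exp(ls[:, 1])
            store["rho"][:, j] = np.tanh(z)

    store["pooled_se"] = _expit(store["mu_se"])
    store["pooled_sp"] = _expit(store["mu_sp"])

    # draw-wise AUC on a thinned subset of retained draws
    from .sroc import auc_from_draws  # local import: sroc depends on this module

    thin = max(1, (C * keep) // max(1, auc_draws))
    flat_idx = np.arange(0, C * keep, thin)
    auc = auc_from_draws(
        store["mu_se"].reshape(-1)[flat_idx],
        store["mu_sp"].reshape(-1)[flat_idx],
        store["sigma_se"].reshape(-1)[flat_idx],
        store["sigma_sp"].reshape(-1)[flat_idx],
        store["rho"].reshape(-1)[flat_idx],
    )
    store["auc"] = auc[None, :]

    summary = summarize_posterior(store)
    summary.acceptance = {
        b: (acc_count[b] / acc_total[b]) if acc_total[b] else float("nan")
        for b in acc_count
    }

    hyper = ["mu_se", "mu_sp", "sigma_se", "sigma_sp"] + (
        ["rho"] if fix_rho is None else []
    )
    summary.rhat = {q: _split_rhat(store[q]) for q in hyper}
    summary.ess = {q: _ess_bulk(store[q]) for q in hyper}
    worst = max(summary.rhat.values())
    if worst > rhat_threshold:
        summary.converged = False
        logger.warning(
            "MCMC flagged non-converged: max split R-hat %.3f > %.2f; "
            "diagnostics: rhat=%s ess=%s acceptance=%s",
            worst, rhat_threshold, summary.rhat, summary.ess, summary.acceptance,
        )
    return summary


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (rank-free version)."""
    C, T = draws.shape
    half = T // 2
    if half < 2:
        return float("nan")
    split = draws[:, : 2 * half].reshape(2 * C, half)
    m, n = split.shape
    means = split.mean(axis=1)
    w = split.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w)) if w > 0 else float("nan")


def _ess_bulk(draws: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(draws)))


def summarize_posterior(
    draws: Mapping[str, np.ndarray],
) -> PosteriorSummary:
    """Median, mean and equal-tailed 95% interval per quantity.

    Derived proportions must be supplied draw-wise (e.g. ``pooled_se``):
    summaries are computed on the draws themselves, never by transforming a
    summary — although for the monotone inverse-logit both routes agree for
    the quantiles.
    """
    quantities: dict[str, QuantitySummary] = {}
    out_draws: dict[str, np.ndarray] = {}
    for name, arr in draws.items():
        flat = np.asarray(arr, dtype=float).reshape(-1)
        if flat.size == 0:
            raise ValueError(f"no draws supplied for {name!r}")
        lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
        quantities[name] = QuantitySummary(
            median=float(med), mean=float(flat.mean()), lo=float(lo), hi=float(hi)
        )
        out_draws[name] = np.asarray(arr, dtype=float)
    return PosteriorSummary(quantities=quantities, draws=out_draws)
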