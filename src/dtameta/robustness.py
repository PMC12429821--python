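"""Descriptive pooling, leave-one-out influence and subgroup analyses.

``simple_pool`` reproduces the descriptive "Overall" rows of the study
table: unweighted arithmetic means of the printed per-study percentages
(a sample-size-weighted variant is reported alongside — the two pooling
conventions disagree and neither is chosen silently for the user).
Leave-one-out refits the Bayesian model k times, omitting one study each
time; subgroup analysis fits it independently per stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .heterogeneity import HeterogeneityResult, logit_effects, q_and_i2
from .model import PosteriorSummary, PriorSpec, fit_mcmc
from .records import ContingencyTable, StudyRecord, reconstruct_record

logger = logging.getLogger(__name__)

#: country -> region map for the geographic stratification
REGION_MAP = {
    "USA": "North America",
    "Canada": "North America",
    "Argentina": "South America",
    "Chile": "South America",
    "Italy": "Europe",
    "Germany": "Europe",
    "The Netherlands": "Europe",
    "United Kingdom": "Europe",
    "Switzerland": "Europe",
    "Spain": "Europe",
    "Greece": "Europe",
    "Belgium": "Europe",
    "Serbia": "Europe",
    "Poland": "Europe",
    "France": "Europe",
    "Ireland": "Europe",
    "Norway": "Europe",
    "Portugal": "Europe",
    "Turkey": "Europe",
    "Japan": "Asia",
    "China": "Asia",
    "Taiwan": "Asia",
    "Iran": "Asia",
}

#: publication-year boundary of the early-vs-late period split
PERIOD_SPLIT_YEAR = 2005

GROUPERS: dict[str, Callable[[StudyRecord], str]] = {
    "modality": lambda r: r.modality,
    "technique": lambda r: f"{r.modality}:{r.technique}",
    "sex_subgroup": lambda r: r.sex_subgroup,
    "region": lambda r: REGION_MAP.get(r.country, "Other"),
    "period": lambda r: (
        "1990-2004" if r.year < PERIOD_SPLIT_YEAR else f"{PERIOD_SPLIT_YEAR}-2025"
    ),
    "design": lambda r: r.design,
}


@dataclass(frozen=True)
class PooledRow:
    """Descriptive pool of printed percentages over a set of records."""

    k: int
    n_total: int
    sen_pct: float
    spe_pct: float
    acc_pct: float
    sen_pct_weighted: float
    spe_pct_weighted: float
    acc_pct_weighted: float
    pct_female: float | None   # n-weighted over non-missing rows (approximate)
    mean_age: float | None     # unweighted over non-missing rows (approximate)


def simple_pool(records: Sequence[StudyRecord]) -> PooledRow:
    """Unweighted means of printed percentages, rounded to one decimal.

    Mirrors the study table's own "Overall" rows; the n-weighted variant is
    carried alongside for comparison.  %female is pooled n-weighted and age
    unweighted, both over non-missing rows only and flagged approximate.
    """
    if not records:
        raise ValueError("cannot pool an empty set of records")
    n_total = sum(r.n for r in records)
    k = len(records)

    def unw(attr: str) -> float:
        return round(sum(getattr(r, attr) for r in records) / k, 1)

    def wtd(attr: str) -> float:
        return round(sum(getattr(r, attr) * r.n for r in records) / n_total, 1)

    fem_rows = [r for r in records if r.pct_female is not None]
    age_rows = [r for r in records if r.mean_age is not None]
    fem = (
        round(sum(r.pct_female * r.n for r in fem_rows) / sum(r.n for r in fem_rows), 1)
        if fem_rows else None
    )
    age = round(sum(r.mean_age for r in age_rows) / len(age_rows), 1) if age_rows else None
    return PooledRow(
        k=k,
        n_total=n_total,
        sen_pct=unw("sen_pct"),
        spe_pct=unw("spe_pct"),
        acc_pct=unw("acc_pct"),
        sen_pct_weighted=wtd("sen_pct"),
        spe_pct_weighted=wtd("spe_pct"),
        acc_pct_weighted=wtd("acc_pct"),
        pct_female=fem,
        mean_age=age,
    )


@dataclass(frozen=True)
class LooEntry:
    excluded: str
    pooled_se_median: float
    pooled_se_lo: float
    pooled_se_hi: float
    pooled_sp_median: float
    pooled_sp_lo: float
    pooled_sp_hi: float


@dataclass
class LooReport:
    entries: list[LooEntry]
    full_se_median: float
    full_sp_median: float

    @property
    def se_range(self) -> tuple[float, float]:
        vals = [e.pooled_se_median for e in self.entries]
        return min(vals), max(vals)

    @property
    def sp_range(self) -> tuple[float, float]:
        vals = [e.pooled_sp_median for e in self.entries]
        return min(vals), max(vals)


def loo_analysis(
    data: Sequence[ContingencyTable],
    labels: Sequence[str] | None = None,
    prior: PriorSpec = PriorSpec(),
    *,
    chains: int = 4,
    iters_per_chain: int = 10_000,
    seed: int = 0,
) -> LooReport:
    """Refit the model k times, omitting one study each; derived seeds per refit."""
    k = len(data)
    if k < 3:
        raise ValueError("leave-one-out needs at least three studies")
    labels = list(labels) if labels is not None else [f"study{i}" for i in range(k)]

    full = fit_mcmc(
        data, prior, chains=chains, iters_per_chain=iters_per_chain, seed=seed
    )
    entries = []
    for i in range(k):
        subset = [t for j, t in enumerate(data) if j != i]
        fit = fit_mcmc(
            subset, prior, chains=chains, iters_per_chain=iters_per_chain,
            seed=seed + 1 + i,
        )
        entries.append(
            LooEntry(
                excluded=labels[i],
                pooled_se_median=fit["pooled_se"].median,
                pooled_se_lo=fit["pooled_se"].lo,
                pooled_se_hi=fit["pooled_se"].hi,
                pooled_sp_median=fit["pooled_sp"].median,
                pooled_sp_lo=fit["pooled_sp"].lo,
                pooled_sp_hi=fit["pooled_sp"].hi,
            )
        )
    return LooReport(
        entries=entries,
        full_se_median=full["pooled_se"].median,
        full_sp_median=full["pooled_sp"].median,
    )


@dataclass
class SubgroupFit:
    group: str
    k: int
    posterior: PosteriorSummary
    heterogeneity_se: HeterogeneityResult | None
    heterogeneity_sp: HeterogeneityResult | None
    rho_fixed: bool


def subgroup_analysis(
    records: Sequence[StudyRecord],
    scheme: str,
    prior: PriorSpec = PriorSpec(),
    *,
    chains: int = 4,
    iters_per_chain: int = 10_000,
    seed: int = 0,
) -> dict[str, SubgroupFit]:
    """Independent model fits per stratum of a grouping scheme.

    All groups share the same priors and iteration budget.  Strata with a
    single study are fitted with the correlation fixed at zero and flagged;
    empty strata cannot arise (every record maps to exactly one group).
    """
    if scheme not in GROUPERS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(GROUPERS)}")
    grouper = GROUPERS[scheme]
    groups: dict[str, list[StudyRecord]] = {}
    for r in records:
        groups.setdefault(grouper(r), []).append(r)

    out: dict[str, SubgroupFit] = {}
    for g_idx, (name, members) in enumerate(sorted(groups.items())):
        tables = [reconstruct_record(r).table for r in members]
        fix = 0.0 if len(tables) < 2 else None
        fit = fit_mcmc(
            tables, prior, chains=chains, iters_per_chain=iters_per_chain,
            seed=seed + 101 * g_idx, fix_rho=fix,
        )
        het_se = het_sp = None
        if len(tables) >= 2:
            het_se = q_and_i2(logit_effects(tables, "sensitivity"))
            het_sp = q_and_i2(logit_effects(tables, "specificity"))
        else:
            logger.warning("subgroup %s has a single study; rho fixed at 0", name)
        out[name] = SubgroupFit(
            group=name,
            k=len(tables),
            posterior=fit,
            heterogeneity_se=het_se,
            heterogeneity_sp=het_sp,
            rho_fixed=fix is not None,
        )
    return out


def ranking_table(fits: dict[str, SubgroupFit]) -> list[tuple[str, float, float]]:
    """Groups ranked by pooled sensitivity, with pooled specificity alongside."""
    rows = [
        (name, f.posterior["pooled_se"].median, f.posterior["pooled_sp"].median)
        for name, f in fits.items()
    ]
    return sorted(rows, key=lambda r: r[1], reverse=True)
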