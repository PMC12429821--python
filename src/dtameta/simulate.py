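"""Forward simulation of the bivariate binomial-normal generative model.

Study-level (logit sensitivity, logit specificity) pairs are drawn from a
bivariate normal; within each study the observed true-positive and
true-negative counts are binomial given the latent accuracies and the
per-study disease strata sizes.  Prevalence is a simulation knob only: the
meta-analytic model conditions on the strata sizes and never models it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import BivariateParams
from .records import ContingencyTable, StudyRecord, derive_metrics


@dataclass(frozen=True)
class CohortSpec:
    """Configuration for one simulated collection of diagnostic studies.

    ``sizes`` and ``prevalences`` may be scalars (shared by all studies) or
    per-study sequences of length ``k``.  Defaults: balanced strata
    (prevalence 0.5) and 100 patients per study.
    """

    k: int
    params: BivariateParams
    sizes: int | Sequence[int] = 100
    prevalences: float | Sequence[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for n in np.atleast_1d(np.asarray(self.sizes)):
            if n < 2:
                raise ValueError("all study sizes must be >= 2")
        for p in np.atleast_1d(np.asarray(self.prevalences, dtype=float)):
            if not 0.0 < p < 1.0:
                raise ValueError("prevalences must lie strictly inside (0, 1)")

    def size_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.sizes, dtype=int), (self.k,)).copy()

    def prevalence_array(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.prevalences, dtype=float), (self.k,)
        ).copy()


@dataclass(frozen=True)
class SimulatedStudy:
    record: StudyRecord
    table: ContingencyTable
    latent_se: float
    latent_sp: float


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_studies(spec: CohortSpec) -> list[SimulatedStudy]:
    """Draw ``spec.k`` studies from the generative model.

    The random stream is split per study index (one spawned child generator
    per study), so increasing ``k`` appends new studies without reshuffling
    the ones already drawn for the same seed.
    """
    p = spec.params
    sizes = spec.size_array()
    prev = spec.prevalence_array()
    # closed-form Cholesky factor; exact degeneracy at |rho| = 1 keeps the
    # latent points on a line, which the correlation tests rely on
    chol = np.array(
        [
            [p.sigma_se, 0.0],
            [p.rho * p.sigma_sp, np.sqrt(max(0.0, 1.0 - p.rho**2)) * p.sigma_sp],
        ]
    )
    children = np.random.SeedSequence(spec.seed).spawn(spec.k)

    out: list[SimulatedStudy] = []
    for i in range(spec.k):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        z = rng.standard_normal(2)
        logit_se, logit_sp = np.array([p.mu_se, p.mu_sp]) + chol @ z
        se, sp = float(_expit(np.array([logit_se]))[0]), float(_expit(np.array([logit_sp]))[0])
        n = int(sizes[i])
        n_d = int(np.clip(round(prev[i] * n), 1, n - 1))
        n_h = n - n_d
        tp = int(rng.binomial(n_d, se))
        tn = int(rng.binomial(n_h, sp))
        table = ContingencyTable(tp=tp, fp=n_h - tn, tn=tn, fn=n_d - tp)
        m = derive_metrics(table)
        record = StudyRecord(
            study_id=f"sim{i:04d}",
            year=2000,
            country="synthetic",
            design="prospective",
            centers="monocentric",
            modality="SE",
            technique="none",
            n=n,
            pct_female=None,
            mean_age=None,
            cad_status="mixed",
            stenosis_cutoff=50,
            sen_pct=round(100.0 * m.sensitivity, 1),
            spe_pct=round(100.0 * m.specificity, 1),
            acc_pct=round(100.0 * m.accuracy, 1),
        )
        out.append(
            SimulatedStudy(record=record, table=table, latent_se=se, latent_sp=sp)
        )
    return out


def truth_frame(studies: Sequence[SimulatedStudy], spec: CohortSpec):
    """Companion truth table (latent accuracies + generating parameters)."""
    import pandas as pd

    p = spec.params
    return pd.DataFrame(
        {
            "study_id": [s.record.study_id for s in studies],
            "latent_se": [s.latent_se for s in studies],
            "latent_sp": [s.latent_sp for s in studies],
            "mu_se": p.mu_se,
            "mu_sp": p.mu_sp,
            "sigma_se": p.sigma_se,
            "sigma_sp": p.sigma_sp,
            "rho": p.rho,
            "seed": spec.seed,
        }
    )
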