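"""Study-level data model for diagnostic-accuracy meta-analysis.

Each record is one published evaluation of a stress test (exercise ECG,
stress echo, SPECT or stress CMR) against coronary angiography.  Primary
studies report sensitivity, specificity and accuracy as percentages; the
underlying 2x2 table (TP/FP/TN/FN) is recovered here by a constrained
integer search, since pooled modelling needs raw counts.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MODALITIES = ("EST", "SE", "SPECT", "CMR")
TECHNIQUES = ("exercise", "dobutamine", "dipyridamole", "adenosine", "dual", "none")
DESIGNS = ("prospective", "retrospective")
CENTERS = ("monocentric", "multicentric")
CAD_STATUS = ("suspected", "known", "mixed")
STENOSIS_CUTOFFS = (50, 60, 70, 75)

#: residual (squared percentage points) above which a reconstruction is flagged
DEFAULT_RESIDUAL_THRESHOLD = 25.0


def _round_half_away(x: float) -> int:
    """Nearest integer, halves rounded away from zero (not banker's rounding)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ContingencyTable:
    """Integer 2x2 diagnostic table: disease stratum (tp, fn), healthy stratum (tn, fp)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.tp + self.fn < 1:
            raise ValueError("diseased stratum empty: tp + fn must be >= 1")
        if self.tn + self.fp < 1:
            raise ValueError("non-diseased stratum empty: tn + fp must be >= 1")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricTriple:
    """Sensitivity, specificity and accuracy as proportions in [0, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(frozen=True)
class StudyRecord:
    """One printed analysis row: cohort descriptors plus summary percentages."""

    study_id: str
    year: int
    country: str
    design: str
    centers: str
    modality: str
    technique: str
    n: int
    pct_female: float | None
    mean_age: float | None
    cad_status: str
    stenosis_cutoff: int | None
    sen_pct: float
    spe_pct: float
    acc_pct: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.centers not in CENTERS:
            raise ValueError(f"unknown centers {self.centers!r}")
        if self.cad_status not in CAD_STATUS:
            raise ValueError(f"unknown cad_status {self.cad_status!r}")
        if self.stenosis_cutoff is not None and self.stenosis_cutoff not in STENOSIS_CUTOFFS:
            raise ValueError(f"unknown stenosis cutoff {self.stenosis_cutoff!r}")
        if self.n < 2:
            raise ValueError("study size n must be >= 2")
        for name in ("sen_pct", "spe_pct", "acc_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.pct_female is not None and not 0.0 <= self.pct_female <= 100.0:
            raise ValueError(f"pct_female must lie in [0, 100], got {self.pct_female}")
        # soft consistency check: printed accuracies carry transcription noise
        lo = min(self.sen_pct, self.spe_pct) - 5.0
        hi = max(self.sen_pct, self.spe_pct) + 5.0
        if not lo <= self.acc_pct <= hi:
            logger.warning(
                "record %s (%s/%s): accuracy %.1f outside soft bounds [%.1f, %.1f]",
                self.study_id, self.modality, self.technique, self.acc_pct, lo, hi,
            )

    @property
    def sex_subgroup(self) -> str:
        """'female_only' iff the cohort is 100% female; missing %female counts as mixed."""
        return "female_only" if self.pct_female == 100.0 else "mixed"


@dataclass(frozen=True)
class Reconstruction:
    """Best-fit integer 2x2 table recovered from printed percentages."""

    table: ContingencyTable
    n_diseased: int
    residual: float
    implied: MetricTriple
    flagged: bool


def derive_metrics(t: ContingencyTable) -> MetricTriple:
    """Sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), accuracy = (tp+tn)/total."""
    return MetricTriple(
        sensitivity=t.tp / t.n_diseased,
        specificity=t.tn / t.n_healthy,
        accuracy=(t.tp + t.tn) / t.total,
    )


def _residual(tp: int, tn: int, d: int, n: int,
              sen_pct: float, spe_pct: float, acc_pct: float) -> float:
    return (
        (100.0 * tp / d - sen_pct) ** 2
        + (100.0 * tn / (n - d) - spe_pct) ** 2
        + (100.0 * (tp + tn) / n - acc_pct) ** 2
    )


def reconstruct_counts(
    n: int,
    sen_pct: float,
    spe_pct: float,
    acc_pct: float,
    *,
    residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
) -> Reconstruction:
    """Recover the integer 2x2 table best matching printed summary percentages.

    For each candidate number of diseased patients ``D`` in ``1..n-1`` the
    implied counts are ``tp = round(sen * D / 100)`` and
    ``tn = round(spe * (n - D) / 100)`` (half away from zero), and the
    candidate's fit is the summed squared deviation of the implied sensitivity,
    specificity and accuracy (in percentage points) from the printed values.
    Ties are broken toward a balanced design (smallest ``|2D - n|``), then
    toward smaller ``D``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    for name, v in (("sen_pct", sen_pct), ("spe_pct", spe_pct), ("acc_pct", acc_pct)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")

    best: tuple[float, int, int] | None = None  # (residual, |2D-n|, D)
    best_counts: tuple[int, int] | None = None
    for d in range(1, n):
        tp = _round_half_away(sen_pct * d / 100.0)
        tn = _round_half_away(spe_pct * (n - d) / 100.0)
        key = (_residual(tp, tn, d, n, sen_pct, spe_pct, acc_pct), abs(2 * d - n), d)
        if best is None or key < best:
            best = key
            best_counts = (tp, tn)

    assert best is not None and best_counts is not None
    resid, _, d = best
    tp, tn = best_counts
    table = ContingencyTable(tp=tp, fp=(n - d) - tn, tn=tn, fn=d - tp)
    flagged = resid > residual_threshold
    if flagged:
        logger.warning(
            "reconstruction residual %.2f exceeds threshold %.2f "
            "(n=%d, sen=%.1f, spe=%.1f, acc=%.1f)",
            resid, residual_threshold, n, sen_pct, spe_pct, acc_pct,
        )
    return Reconstruction(
        table=table,
        n_diseased=d,
        residual=resid,
        implied=derive_metrics(table),
        flagged=flagged,
    )


def reconstruct_record(
    rec: StudyRecord, *, residual_threshold: float = DEFAULT_RESIDUAL_THRESHOLD
) -> Reconstruction:
    return reconstruct_counts(
        rec.n, rec.sen_pct, rec.spe_pct, rec.acc_pct,
        residual_threshold=residual_threshold,
    )


def cohen_kappa(p_o: float, p_e: float) -> float:
    """Chance-corrected agreement: (p_o - p_e) / (1 - p_e)."""
    if not 0.0 <= p_o <= 1.0:
        raise ValueError("p_o must lie in [0, 1]")
    if not 0.0 <= p_e < 1.0:
        raise ValueError("p_e must lie in [0, 1); kappa is undefined at p_e = 1")
    return (p_o - p_e) / (1.0 - p_e)


_HEADER = [
    "study_id", "year", "country", "design", "centers", "modality", "technique",
    "n", "pct_female", "mean_age", "cad_status", "stenosis_cutoff",
    "sen_pct", "spe_pct", "acc_pct",
]


def _parse_row(row: dict[str, str], lineno: int) -> StudyRecord:
    def opt_float(key: str) -> float | None:
        v = row[key].strip()
        return float(v) if v else None

    def opt_int(key: str) -> int | None:
        v = row[key].strip()
        return int(float(v)) if v else None

    try:
        return StudyRecord(
            study_id=row["study_id"].strip(),
            year=int(row["year"]),
            country=row["country"].strip(),
            design=row["design"].strip(),
            centers=row["centers"].strip(),
            modality=row["modality"].strip(),
            technique=row["technique"].strip(),
            n=int(row["n"]),
            pct_female=opt_float("pct_female"),
            mean_age=opt_float("mean_age"),
            cad_status=row["cad_status"].strip(),
            stenosis_cutoff=opt_int("stenosis_cutoff"),
            sen_pct=float(row["sen_pct"]),
            spe_pct=float(row["spe_pct"]),
            acc_pct=float(row["acc_pct"]),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed study row at line {lineno}: {exc}") from exc


@dataclass
class ValidationReport:
    """Census produced while loading a study table."""

    n_rows: int
    modality_counts: dict[str, int]
    technique_counts: dict[tuple[str, str], int]
    missing: dict[str, int]
    n_unique_cohorts: int
    total_unique_patients: int
    warnings: list[str] = field(default_factory=list)


def load_fixture(path: str | Path | None = None) -> list[StudyRecord]:
    """Load study records from CSV; ``None`` loads the packaged study table."""
    if path is None:
        src = resources.files("dtameta").joinpath("data/studies.csv")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")

    lines = text.splitlines()
    reader = csv.DictReader(lines)
    if reader.fieldnames != _HEADER:
        raise ValueError(
            f"unexpected CSV header: {reader.fieldnames!r}; expected {_HEADER!r}"
        )
    return [_parse_row(row, lineno) for lineno, row in enumerate(reader, start=2)]


def validate_records(records: Sequence[StudyRecord]) -> ValidationReport:
    modality_counts: dict[str, int] = {}
    technique_counts: dict[tuple[str, str], int] = {}
    missing = {"pct_female": 0, "mean_age": 0, "stenosis_cutoff": 0}
    cohorts: dict[tuple[str, int], int] = {}
    for r in records:
        modality_counts[r.modality] = modality_counts.get(r.modality, 0) + 1
        key = (r.modality, r.technique)
        technique_counts[key] = technique_counts.get(key, 0) + 1
        if r.pct_female is None:
            missing["pct_female"] += 1
        if r.mean_age is None:
            missing["mean_age"] += 1
        if r.stenosis_cutoff is None:
            missing["stenosis_cutoff"] += 1
        cohorts[(r.study_id, r.n)] = r.n
    return ValidationReport(
        n_rows=len(records),
        modality_counts=modality_counts,
        technique_counts=technique_counts,
        missing=missing,
        n_unique_cohorts=len(cohorts),
        total_unique_patients=sum(cohorts.values()),
    )


def filter_records(
    records: Iterable[StudyRecord],
    *,
    modality: str | None = None,
    technique: str | None = None,
    sex_subgroup: str | None = None,
) -> list[StudyRecord]:
    out = []
    for r in records:
        if modality is not None and r.modality != modality:
            continue
        if technique is not None and r.technique != technique:
            continue
        if sex_subgroup is not None and r.sex_subgroup != sex_subgroup:
            continue
        out.append(r)
    return out
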