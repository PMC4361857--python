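"""Collagen quality control and age-class eligibility filtering.

Diagenetically altered bone collagen is screened out with the standard
elemental indicators of pure collagen: atomic C:N within [2.9, 3.6],
atomic C:S within [300, 900], atomic N:S within [100, 300], and weight %S
within [0.15, 0.35].  Bears aged two years or younger are excluded because
nursing inflates the nitrogen isotope signature; specimens of unknown age
are kept only when bone size marks them as clearly adult.

All interval bounds are closed (a boundary value passes) and configurable.
A criterion whose inputs are missing is recorded as "not evaluable" and, by
default, does not fail the record; set ``require_sulfur_qc`` to demand the
sulfur criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import AgeClass, SpecimenRecord


@dataclass(frozen=True)
class QCThresholds:
    cn_range: tuple[float, float] = (2.9, 3.6)
    cs_range: tuple[float, float] = (300.0, 900.0)
    ns_range: tuple[float, float] = (100.0, 300.0)
    pctS_range: tuple[float, float] = (0.15, 0.35)
    min_age_exclusive_years: float = 2.0
    require_sulfur_qc: bool = False

    def __post_init__(self) -> None:
        for name in ("cn_range", "cs_range", "ns_range", "pctS_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")


@dataclass
class QCFailure:
    criterion: str
    observed: float | None
    allowed: tuple[float, float]


@dataclass
class QCResult:
    specimen_id: str
    passed: bool
    failures: list[QCFailure] = field(default_factory=list)
    not_evaluable: list[str] = field(default_factory=list)


# sulfur-dependent criteria, skippable when %S was never measured
_SULFUR_CRITERIA = {"CS", "NS", "pctS"}


def assess_collagen(record: SpecimenRecord, thresholds: QCThresholds | None = None) -> QCResult:
    """Check one specimen against every collagen-purity criterion.

    Closed intervals: ``lo <= x <= hi`` passes.  Missing inputs make a
    criterion "not evaluable"; such criteria fail the record only under
    ``require_sulfur_qc`` (and then only the sulfur ones — C:N is always
    required when %C/%N exist, which they do for any measured collagen).
    """
    th = thresholds or QCThresholds()
    atomic = record.atomic
    checks = {
        "CN": (atomic["CN"], th.cn_range),
        "CS": (atomic["CS"], th.cs_range),
        "NS": (atomic["NS"], th.ns_range),
        "pctS": (record.pct_S, th.pctS_range),
    }
    failures: list[QCFailure] = []
    not_evaluable: list[str] = []
    for name, (value, (lo, hi)) in checks.items():
        if value is None:
            if name in _SULFUR_CRITERIA and th.require_sulfur_qc:
                failures.append(QCFailure(name, None, (lo, hi)))
            else:
                not_evaluable.append(name)
            continue
        if not (lo <= value <= hi):
            failures.append(QCFailure(name, value, (lo, hi)))
    return QCResult(record.specimen_id, passed=not failures, failures=failures,
                    not_evaluable=not_evaluable)


def filter_age(
    records: Sequence[SpecimenRecord], thresholds: QCThresholds | None = None
) -> tuple[list[SpecimenRecord], list[tuple[SpecimenRecord, str]]]:
    """Drop nursing-age and unverifiable-age specimens, preserving order.

    Known age <= 2 years is excluded; unknown age is excluded unless the
    specimen was judged clearly adult by bone size (kept, with a provenance
    note in the exclusion log's retained counterpart).
    """
    th = thresholds or QCThresholds()
    retained: list[SpecimenRecord] = []
    excluded: list[tuple[SpecimenRecord, str]] = []
    for rec in records:
        if rec.age_years is not None:
            if rec.age_years <= th.min_age_exclusive_years:
                excluded.append((rec, f"age {rec.age_years} <= {th.min_age_exclusive_years} years"))
                continue
            retained.append(rec)
            continue
        if rec.age_class in (AgeClass.CUB, AgeClass.SUBADULT):
            excluded.append((rec, f"age class {rec.age_class.value}"))
        elif rec.age_class == AgeClass.UNKNOWN:
            excluded.append((rec, "age unknown and not verifiable by bone size"))
        else:  # ADULT or UNKNOWN_ADULT_BY_BONE_SIZE
            retained.append(rec)
    return retained, excluded


def run_qc(
    records: Sequence[SpecimenRecord], thresholds: QCThresholds | None = None
) -> tuple[list[SpecimenRecord], pd.DataFrame]:
    """Age filter then collagen screening; returns (clean records, exclusion log).

    The log has one row per failed criterion (or one row for an age
    exclusion) with columns specimen_id, stage, criterion, observed,
    allowed_lo, allowed_hi, reason — machine-readable and CSV-ready.
    An empty retained set is legal (the log tells the story).
    """
    th = thresholds or QCThresholds()
    log_rows: list[dict] = []
    age_ok, age_excluded = filter_age(records, th)
    for rec, reason in age_excluded:
        log_rows.append(
            {"specimen_id": rec.specimen_id, "stage": "age", "criterion": "age",
             "observed": rec.age_years, "allowed_lo": None, "allowed_hi": None,
             "reason": reason}
        )
    clean: list[SpecimenRecord] = []
    for rec in age_ok:
        result = assess_collagen(rec, th)
        if result.passed:
            clean.append(rec)
            continue
        for f in result.failures:
            log_rows.append(
                {"specimen_id": rec.specimen_id, "stage": "collagen",
                 "criterion": f.criterion, "observed": f.observed,
                 "allowed_lo": f.allowed[0], "allowed_hi": f.allowed[1],
                 "reason": f"{f.criterion} outside [{f.allowed[0]}, {f.allowed[1]}]"}
            )
    log = pd.DataFrame(
        log_rows,
        columns=["specimen_id", "stage", "criterion", "observed",
                 "allowed_lo", "allowed_hi", "reason"],
    )
    return clean, log


def write_qc_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False)
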