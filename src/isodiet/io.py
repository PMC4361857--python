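"""CSV interchange for specimen and source tables.

`specimens.csv` columns: specimen_id, region, site, year_lo, year_hi,
age_class, age_years, d13C, d15N, d34S, pct_C, pct_N, pct_S (blank = missing).
`sources.csv` columns: sample_id, category, region, d13C, d15N, d34S,
pct_C, pct_N, pct_S.  UTF-8, header row required, '.' decimal point.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import AgeClass, IsotopeVector, Region, SourceSample, SpecimenRecord

SPECIMEN_COLUMNS = [
    "specimen_id", "region", "site", "year_lo", "year_hi", "age_class",
    "age_years", "d13C", "d15N", "d34S", "pct_C", "pct_N", "pct_S",
]
SOURCE_COLUMNS = [
    "sample_id", "category", "region", "d13C", "d15N", "d34S",
    "pct_C", "pct_N", "pct_S",
]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
        return float(value)
    return float(value)


def read_specimens(path: str | Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, dtype={"specimen_id": str, "site": str})
    records = []
    for row in df.to_dict("records"):
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                region=Region(row["region"]),
                site=str(row.get("site") or ""),
                year_lo=_opt(row.get("year_lo")),
                year_hi=_opt(row.get("year_hi")),
                age_class=AgeClass(row["age_class"]) if isinstance(row.get("age_class"), str) else AgeClass.UNKNOWN,
                age_years=_opt(row.get("age_years")),
                isotopes=IsotopeVector(
                    d13C=_opt(row.get("d13C")),
                    d15N=_opt(row.get("d15N")),
                    d34S=_opt(row.get("d34S")),
                ),
                pct_C=_opt(row.get("pct_C")),
                pct_N=_opt(row.get("pct_N")),
                pct_S=_opt(row.get("pct_S")),
            )
        )
    return records


def write_specimens(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "region": r.region.value,
                "site": r.site,
                "year_lo": r.year_lo,
                "year_hi": r.year_hi,
                "age_class": r.age_class.value,
                "age_years": r.age_years,
                "d13C": r.isotopes.d13C,
                "d15N": r.isotopes.d15N,
                "d34S": r.isotopes.d34S,
                "pct_C": r.pct_C,
                "pct_N": r.pct_N,
                "pct_S": r.pct_S,
            }
        )
    pd.DataFrame(rows, columns=SPECIMEN_COLUMNS).to_csv(path, index=False)


def read_sources(path: str | Path) -> list[SourceSample]:
    df = pd.read_csv(path, dtype={"sample_id": str, "category": str})
    samples = []
    for row in df.to_dict("records"):
        samples.append(
            SourceSample(
                sample_id=str(row["sample_id"]),
                category=str(row["category"]),
                region=Region(row["region"]),
                isotopes=IsotopeVector(
                    d13C=_opt(row.get("d13C")),
                    d15N=_opt(row.get("d15N")),
                    d34S=_opt(row.get("d34S")),
                ),
                pct_C=_opt(row.get("pct_C")),
                pct_N=_opt(row.get("pct_N")),
                pct_S=_opt(row.get("pct_S")),
            )
        )
    return samples


def write_sources(samples: Sequence[SourceSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "category": s.category,
                "region": s.region.value,
                "d13C": s.isotopes.d13C,
                "d15N": s.isotopes.d15N,
                "d34S": s.isotopes.d34S,
                "pct_C": s.pct_C,
                "pct_N": s.pct_N,
                "pct_S": s.pct_S,
            }
        )
    pd.DataFrame(rows, columns=SOURCE_COLUMNS).to_csv(path, index=False)
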