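"""Core data model and δ-notation arithmetic for collagen isotope analysis.

Isotope ratios are expressed throughout in δ notation: the per-mil deviation
of a sample's heavy/light isotope ratio from an international standard
(VPDB for carbon, atmospheric N₂ for nitrogen, VCDT for sulfur, each taken
as the heavy/light ratio ³⁴S/³²S etc.).

Records carry their isotope channels explicitly: a missing channel is
``None``, never imputed, and every downstream stage operates on the
intersection of channels available in all records entering that stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Channel order used everywhere a per-channel vector appears.
CHANNELS = ("d13C", "d15N", "d34S")

#: Atomic masses (u) fixed so C:N ratios are bit-reproducible.
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "S": 32.06}


class Region(str, Enum):
    """Study regions. Exactly two; anything else is a validation error."""

    WESTERN = "western"
    EASTERN = "eastern"


class AgeClass(str, Enum):
    ADULT = "adult"
    SUBADULT = "subadult"
    CUB = "cub"
    UNKNOWN_ADULT_BY_BONE_SIZE = "unknown_adult_by_bone_size"
    UNKNOWN = "unknown"


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Convert a raw heavy/light isotope ratio to a δ value in ‰.

    δ = (R_sample / R_standard − 1) × 1000.

    Raises
    ------
    ValueError
        If either ratio is not strictly positive.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError("isotope ratios must be strictly positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`: recover R_sample from δ (‰)."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be strictly positive")
    return (delta / 1000.0 + 1.0) * r_standard


def atomic_ratios(
    pct_c: float | None, pct_n: float | None, pct_s: float | None
) -> dict[str, float | None]:
    """Atomic C:N, C:S and N:S ratios from weight percents.

    Atomic ratio X:Y = (pct_X / mass_X) / (pct_Y / mass_Y).  A ratio whose
    numerator or denominator percent is missing or whose denominator is zero
    is reported as ``None`` (missing), never raised as a division error.
    """

    def mol(pct: float | None, element: str) -> float | None:
        if pct is None or not math.isfinite(pct) or pct < 0:
            return None
        return pct / ATOMIC_MASS[element]

    c, n, s = mol(pct_c, "C"), mol(pct_n, "N"), mol(pct_s, "S")

    def ratio(num: float | None, den: float | None) -> float | None:
        if num is None or den is None or den == 0:
            return None
        return num / den

    return {"CN": ratio(c, n), "CS": ratio(c, s), "NS": ratio(n, s)}


@dataclass(frozen=True)
class IsotopeVector:
    """Per-specimen δ values (‰); a ``None`` channel was not measured."""

    d13C: float | None = None
    d15N: float | None = None
    d34S: float | None = None

    def __post_init__(self) -> None:
        if all(getattr(self, ch) is None for ch in CHANNELS):
            raise ValueError("at least one isotope channel must be present")
        for ch in CHANNELS:
            v = getattr(self, ch)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{ch} must be finite, got {v!r}")

    @property
    def channels(self) -> tuple[str, ...]:
        """Channels actually measured, in canonical order."""
        return tuple(ch for ch in CHANNELS if getattr(self, ch) is not None)

    def as_array(self, channels: Sequence[str]) -> np.ndarray:
        """Values for `channels`; raises if any requested channel is missing."""
        out = []
        for ch in channels:
            v = getattr(self, ch)
            if v is None:
                raise KeyError(f"channel {ch} not measured")
            out.append(v)
        return np.asarray(out, dtype=float)


@dataclass
class SpecimenRecord:
    """One consumer bone-collagen measurement with its QC inputs."""

    specimen_id: str
    region: Region
    isotopes: IsotopeVector
    year_lo: float | None = None
    year_hi: float | None = None
    site: str = ""
    age_class: AgeClass = AgeClass.UNKNOWN
    age_years: float | None = None
    pct_C: float | None = None
    pct_N: float | None = None
    pct_S: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.region, str):
            self.region = Region(self.region)
        if isinstance(self.age_class, str):
            self.age_class = AgeClass(self.age_class)
        for name in ("pct_C", "pct_N", "pct_S"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if self.year_lo is not None and self.year_hi is not None:
            if self.year_lo > self.year_hi:
                raise ValueError("year_lo must not exceed year_hi")

    @property
    def atomic(self) -> dict[str, float | None]:
        """Atomic C:N, C:S, N:S derived from the weight percents."""
        return atomic_ratios(self.pct_C, self.pct_N, self.pct_S)

    @property
    def year_mid(self) -> float | None:
        if self.year_lo is None or self.year_hi is None:
            return None
        return 0.5 * (self.year_lo + self.year_hi)


@dataclass
class SourceSample:
    """One diet-item measurement (isotopes + elemental concentrations)."""

    sample_id: str
    category: str
    region: Region
    isotopes: IsotopeVector
    pct_C: float | None = None
    pct_N: float | None = None
    pct_S: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.region, str):
            self.region = Region(self.region)
        if not self.category:
            raise ValueError("category must be nonempty")
        for name in ("pct_C", "pct_N", "pct_S"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 100):
                raise ValueError(f"{name} must lie in (0, 100], got {v}")


#: weight-percent field per channel, for concentration-dependent mixing
PCT_FIELD = {"d13C": "pct_C", "d15N": "pct_N", "d34S": "pct_S"}


@dataclass
class SourceGroup:
    """A pooled diet category entering the mixing model.

    Per isotope channel j the group carries a mean ``mu[j]`` (‰), a standard
    deviation ``omega[j]`` (‰) and an elemental concentration ``q[j]``
    expressed as a fraction of dry mass in (0, 1].
    """

    name: str
    mu: dict[str, float]
    omega: dict[str, float]
    q: dict[str, float]
    n: int = 0

    def __post_init__(self) -> None:
        if set(self.mu) != set(self.omega) or set(self.mu) != set(self.q):
            raise ValueError("mu, omega and q must cover identical channels")
        for ch, w in self.omega.items():
            if w < 0:
                raise ValueError(f"omega[{ch}] must be >= 0")
        for ch, qv in self.q.items():
            if not (0 < qv <= 1):
                raise ValueError(f"q[{ch}] must lie in (0, 1], got {qv}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in CHANNELS if ch in self.mu)

    @classmethod
    def from_samples(cls, name: str, samples: Sequence[SourceSample]) -> "SourceGroup":
        """Pool individual samples: per-channel mean/SD of δ, mean concentration.

        Only channels measured in *every* member sample are retained, so the
        group's channel set is the intersection.  SD is the ddof=1 sample SD
        (0 when n=1).
        """
        if not samples:
            raise ValueError("cannot pool an empty sample list")
        chans = set(CHANNELS)
        for s in samples:
            chans &= set(s.isotopes.channels)
        if not chans:
            raise ValueError(f"no shared isotope channels in group {name!r}")
        mu, omega, q = {}, {}, {}
        for ch in sorted(chans, key=CHANNELS.index):
            vals = np.array([getattr(s.isotopes, ch) for s in samples], float)
            mu[ch] = float(vals.mean())
            omega[ch] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            pcts = [getattr(s, PCT_FIELD[ch]) for s in samples]
            pcts = [p for p in pcts if p is not None]
            if not pcts:
                raise ValueError(f"group {name!r} lacks {PCT_FIELD[ch]} values")
            q[ch] = float(np.mean(pcts)) / 100.0
        return cls(name=name, mu=mu, omega=omega, q=q, n=len(samples))


@dataclass
class ValidationIssue:
    record_id: str
    field: str
    message: str


def validate_dataset(
    records: Iterable[SpecimenRecord | SourceSample],
) -> list[ValidationIssue]:
    """Report-only validation: missing fields, non-finite values, bad labels.

    Never mutates its input; an empty report means the dataset is clean.
    Because the record constructors already enforce hard invariants, this
    catches the soft problems a CSV can smuggle in (NaN percents, NaN δ
    written as a real float, unexpected region strings on raw dicts).
    """
    issues: list[ValidationIssue] = []
    for rec in records:
        rid = getattr(rec, "specimen_id", None) or getattr(rec, "sample_id", "?")
        if not isinstance(rec.region, Region):
            issues.append(ValidationIssue(rid, "region", f"unknown region {rec.region!r}"))
        for ch in CHANNELS:
            v = getattr(rec.isotopes, ch)
            if v is not None and not math.isfinite(v):
                issues.append(ValidationIssue(rid, ch, f"non-finite value {v!r}"))
        for name in ("pct_C", "pct_N", "pct_S"):
            v = getattr(rec, name, None)
            if v is not None and not math.isfinite(v):
                issues.append(ValidationIssue(rid, name, f"non-finite value {v!r}"))
        if not rec.isotopes.channels:
            issues.append(ValidationIssue(rid, "isotopes", "no channel measured"))
    return issues


def shared_channels(*channel_sets: Iterable[str]) -> tuple[str, ...]:
    """Intersection of channel collections, in canonical order."""
    common = set(CHANNELS)
    for cs in channel_sets:
        common &= set(cs)
    return tuple(ch for ch in CHANNELS if ch in common)
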