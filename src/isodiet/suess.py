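"""Temporal (Suess-effect) correction of modern source isotope values.

Fossil-fuel CO₂ has depleted atmospheric — and hence biospheric — δ¹³C over
the industrial era, so diet items measured today sit on a lighter carbon
scale than the tissues of animals that lived centuries ago.  Before fitting
a historical consumer group, modern source means are shifted *up* onto that
period's scale (older periods → more positive δ¹³C); the modern reference
period receives no correction.  δ³⁴S is never corrected: there is no
evidence of temporal variation on that channel.

Two modes:

* ``per_period_offsets`` — explicit ‰ offsets per period (the study's
  expected shifts, Period 1 +1.6‰ and Period 2 +0.3‰ relative to the modern
  period, ship as defaults), optionally including small δ¹⁵N offsets capped
  in magnitude.
* ``reference_curve`` — a (year → atmospheric δ¹³C anomaly) table, linearly
  interpolated; the correction is
  D(year) = anomaly(year) − anomaly(reference_year), zero at the reference
  year and non-negative before it for any monotone declining curve.

The default curve below is a *stylized* rendering of the industrial-era
atmospheric δ¹³C decline (~1.8‰ pre-industrial → 2010s), shipped so the
curve mode runs out of the box; it is not a measured data product and
should be replaced with one for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import SourceGroup

#: Stylized atmospheric δ13C anomaly nodes (year, ‰ relative to pre-industrial).
DEFAULT_SUESS_CURVE: tuple[tuple[float, float], ...] = (
    (1000.0, 0.00),
    (1700.0, 0.00),
    (1800.0, -0.05),
    (1850.0, -0.10),
    (1900.0, -0.30),
    (1940.0, -0.50),
    (1960.0, -0.65),
    (1980.0, -1.00),
    (2000.0, -1.45),
    (2010.0, -1.65),
    (2020.0, -1.85),
)

#: Default modern reference year: midpoint of the post-1996 sampling era.
DEFAULT_REFERENCE_YEAR = 2005.0


@dataclass(frozen=True)
class CorrectionConfig:
    mode: str = "per_period_offsets"  # or "reference_curve"
    d13C_offset: Mapping[int, float] = field(
        default_factory=lambda: {1: 1.6, 2: 0.3, 3: 0.0}
    )
    d15N_offset: Mapping[int, float] = field(default_factory=dict)
    d15N_offset_cap: float = 0.4
    curve: Sequence[tuple[float, float]] = DEFAULT_SUESS_CURVE
    reference_year: float = DEFAULT_REFERENCE_YEAR

    def __post_init__(self) -> None:
        if self.mode not in ("per_period_offsets", "reference_curve"):
            raise ValueError(f"unknown correction mode {self.mode!r}")
        for p, v in self.d13C_offset.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite d13C offset for period {p}")
        for p, v in self.d15N_offset.items():
            if abs(v) > self.d15N_offset_cap + 1e-12:
                raise ValueError(
                    f"|d15N offset| for period {p} exceeds cap {self.d15N_offset_cap}‰"
                )
        years = [y for y, _ in self.curve]
        if sorted(years) != list(years) or len(set(years)) != len(years):
            raise ValueError("curve years must be strictly increasing")


def suess_offset(year: float, config: CorrectionConfig | None = None) -> float:
    """δ¹³C correction (‰) to add to modern values for tissue grown in `year`.

    Curve mode only; linear interpolation between nodes, no extrapolation.
    Zero at the reference year; ≥ 0 before it for a declining curve.
    """
    cfg = config or CorrectionConfig(mode="reference_curve")
    if cfg.mode != "reference_curve":
        raise ValueError("suess_offset(year) requires reference_curve mode; "
                         "use period_offset() for per-period mode")
    years = np.array([y for y, _ in cfg.curve], float)
    anom = np.array([a for _, a in cfg.curve], float)
    for y in (year, cfg.reference_year):
        if not (years[0] <= y <= years[-1]):
            raise ValueError(f"year {y} outside curve coverage "
                             f"[{years[0]}, {years[-1]}]; no extrapolation")
    a_year = float(np.interp(year, years, anom))
    a_ref = float(np.interp(cfg.reference_year, years, anom))
    return a_year - a_ref


def period_offset(period: int, config: CorrectionConfig, channel: str = "d13C") -> float:
    """Per-period offset (‰) for the given channel; δ³⁴S is always 0."""
    if channel == "d34S":
        return 0.0
    table = config.d13C_offset if channel == "d13C" else config.d15N_offset
    if channel == "d13C" and period not in table:
        raise ValueError(f"no d13C offset configured for period {period}")
    return float(table.get(period, 0.0))


def correct_sources_for_period(
    groups: Sequence[SourceGroup],
    period: int,
    config: CorrectionConfig | None = None,
    period_year: float | None = None,
) -> list[SourceGroup]:
    """Shift modern source-group means onto a historical period's scale.

    Adds the period's δ¹³C offset (and any configured δ¹⁵N offset) to every
    group mean μ; SDs ω and concentrations q are untouched, and δ³⁴S means
    are bit-identical before and after.  In curve mode `period_year` (e.g.
    the period's midpoint year) selects the offset.
    """
    cfg = config or CorrectionConfig()
    if cfg.mode == "reference_curve":
        if period_year is None:
            raise ValueError("curve mode needs period_year")
        off13 = suess_offset(period_year, cfg)
        off15 = 0.0
    else:
        off13 = period_offset(period, cfg, "d13C")
        off15 = period_offset(period, cfg, "d15N")
    out = []
    for g in groups:
        mu = dict(g.mu)
        if "d13C" in mu:
            mu["d13C"] = mu["d13C"] + off13
        if "d15N" in mu and off15:
            mu["d15N"] = mu["d15N"] + off15
        out.append(SourceGroup(name=g.name, mu=mu, omega=dict(g.omega),
                               q=dict(g.q), n=g.n))
    return out
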