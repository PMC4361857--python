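"""End-to-end orchestration: period assignment, time series, full pipeline.

The historical strata are region-specific: Period 1 (pre-development) ends
in 1890 in the west and 1920 in the east; Period 2 (early development) is
1931–1942 and Period 3 (post-development) is 1996 onward in both regions.
A specimen is assigned to a period only when its whole dated year interval
lies inside one bin; intervals straddling a cutoff are conservatively left
unassigned (and logged), never snapped to their midpoint.

``run_pipeline`` composes the stages in analysis order — QC → source
distinguishability & pooling → temporal correction → per region × period
mixing-model fit → nonparametric period comparisons → time-series binning
with a change-point readout — and emits a provenance record (seed,
thresholds, versions) sufficient to replay every number.  The change-point
fit is a numerical formalization of what the original analysis did by eye:
a single-break piecewise-constant least squares on bin means.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import Region, SourceGroup, SpecimenRecord
from .grouping import merge_sources, pairwise_source_tests
from .mixing import (DiscriminationFactor, MixingModelConfig, PosteriorResult,
                     fit_mixing_model, hdr_overlap_letters)
from .qc import QCThresholds, run_qc
from .ranktests import kruskal_wallis, steel_dwass, wilcoxon_rank_sum
from .simulate import Scenario, generate_dataset
from .suess import CorrectionConfig, correct_sources_for_period


@dataclass(frozen=True)
class PeriodScheme:
    """Region-specific year cutoffs mapping year intervals to periods."""

    period1_end: Mapping[str, float] = field(
        default_factory=lambda: {"western": 1890.0, "eastern": 1920.0}
    )
    period2: tuple[float, float] = (1931.0, 1942.0)
    period3_start: float = 1996.0

    def bins(self, region: str | Region) -> dict[int, tuple[float, float]]:
        region = Region(region).value
        return {
            1: (-np.inf, self.period1_end[region]),   # [lo, hi): strictly before
            2: (self.period2[0], self.period2[1]),    # closed
            3: (self.period3_start, np.inf),          # closed at start
        }


def assign_period(
    year_lo: float, year_hi: float, region: str | Region,
    scheme: PeriodScheme | None = None,
) -> int | None:
    """Period containing the *whole* interval [year_lo, year_hi], else None."""
    scheme = scheme or PeriodScheme()
    b = scheme.bins(region)
    if year_hi < b[1][1]:
        return 1
    if b[2][0] <= year_lo and year_hi <= b[2][1]:
        return 2
    if year_lo >= b[3][0]:
        return 3
    return None


def split_by_period(
    specimens: Sequence[SpecimenRecord], scheme: PeriodScheme | None = None
) -> tuple[dict[tuple[str, int], list[SpecimenRecord]], list[SpecimenRecord]]:
    """Group specimens by (region, period); undatable/straddling go to the rest."""
    scheme = scheme or PeriodScheme()
    groups: dict[tuple[str, int], list[SpecimenRecord]] = {}
    unassigned: list[SpecimenRecord] = []
    for rec in specimens:
        if rec.year_lo is None or rec.year_hi is None:
            unassigned.append(rec)
            continue
        period = assign_period(rec.year_lo, rec.year_hi, rec.region, scheme)
        if period is None:
            unassigned.append(rec)
        else:
            groups.setdefault((rec.region.value, period), []).append(rec)
    return groups, unassigned


@dataclass
class BinnedSeries:
    channel: str
    table: pd.DataFrame   # columns: bin, year_lo, year_hi, year_mid, mean, sd, n


def binned_series(
    specimens: Sequence[SpecimenRecord],
    channel: str,
    bin_edges: Sequence[float] | None = None,
) -> BinnedSeries:
    """Mean ± SD per time bin for one isotope channel, sorted by midpoint year.

    Bins are either user-supplied year edges, or — by default — the natural
    (site, year interval) groups the specimens arrive with.  SD is reported
    as NaN when a bin holds a single specimen.
    """
    rows = []
    usable = [r for r in specimens
              if r.year_mid is not None and getattr(r.isotopes, channel) is not None]
    if not usable:
        return BinnedSeries(channel, pd.DataFrame(
            columns=["bin", "year_lo", "year_hi", "year_mid", "mean", "sd", "n"]))
    if bin_edges is not None:
        edges = np.asarray(bin_edges, float)
        groups: dict[int, list[SpecimenRecord]] = {}
        for r in usable:
            i = int(np.searchsorted(edges, r.year_mid, side="right")) - 1
            if 0 <= i < len(edges) - 1:
                groups.setdefault(i, []).append(r)
        for i, recs in groups.items():
            vals = np.array([getattr(r.isotopes, channel) for r in recs])
            rows.append({"bin": f"[{edges[i]:g},{edges[i+1]:g})",
                         "year_lo": edges[i], "year_hi": edges[i + 1],
                         "year_mid": 0.5 * (edges[i] + edges[i + 1]),
                         "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                         "n": len(vals)})
    else:
        groups2: dict[tuple[str, float, float], list[SpecimenRecord]] = {}
        for r in usable:
            groups2.setdefault((r.site, r.year_lo, r.year_hi), []).append(r)
        for (site, ylo, yhi), recs in groups2.items():
            vals = np.array([getattr(r.isotopes, channel) for r in recs])
            rows.append({"bin": site, "year_lo": ylo, "year_hi": yhi,
                         "year_mid": 0.5 * (ylo + yhi),
                         "mean": vals.mean(),
                         "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                         "n": len(vals)})
    table = pd.DataFrame(rows).sort_values("year_mid", ignore_index=True)
    return BinnedSeries(channel, table)


@dataclass
class ChangePointResult:
    year_interval: tuple[float, float] | None   # between-bin bracket of the break
    break_index: int | None                     # first bin after the break
    sse_profile: list[float]
    no_change: bool


def change_point(series: BinnedSeries) -> ChangePointResult:
    """Single change-point, piecewise-constant least squares on bin means.

    Bin means are weighted by bin sample size.  Returns the between-bin year
    interval bracketing the optimal break and the SSE profile over candidate
    breaks.  A flat profile (all candidate SSEs equal the no-break SSE) is
    flagged ``no_change``.  Requires ≥ 4 bins.
    """
    t = series.table
    if len(t) < 4:
        raise ValueError("change-point readout needs at least 4 bins")
    y = t["mean"].to_numpy(float)
    w = t["n"].to_numpy(float)

    def wsse(seg_y, seg_w):
        m = np.average(seg_y, weights=seg_w)
        return float((seg_w * (seg_y - m) ** 2).sum())

    sse0 = wsse(y, w)
    profile = []
    for b in range(1, len(y)):   # break before bin b
        profile.append(wsse(y[:b], w[:b]) + wsse(y[b:], w[b:]))
    best = int(np.argmin(profile)) + 1
    if np.allclose(profile, sse0):
        return ChangePointResult(None, None, profile, True)
    lo = float(t["year_hi"].iloc[best - 1])
    hi = float(t["year_lo"].iloc[best])
    if lo > hi:   # overlapping bins: fall back to midpoints
        lo, hi = sorted((float(t["year_mid"].iloc[best - 1]),
                         float(t["year_mid"].iloc[best])))
    return ChangePointResult((lo, hi), best, profile, False)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    scenario: Scenario | None = None             # synthetic input ...
    specimens_csv: str | None = None             # ... or CSV inputs
    sources_csv: Mapping[str, str] | None = None  # region -> csv path
    qc: QCThresholds = field(default_factory=QCThresholds)
    scheme: PeriodScheme = field(default_factory=PeriodScheme)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    tdf: DiscriminationFactor = field(default_factory=DiscriminationFactor)
    model: MixingModelConfig = field(default_factory=MixingModelConfig)
    knn_k: int = 3
    knn_n_perm: int = 999
    family_alpha: float = 0.05
    # per-period source availability: category names to drop per period
    unavailable: Mapping[int, tuple[str, ...]] = field(
        default_factory=lambda: {1: ("corn",)}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.scenario is None and self.specimens_csv is None:
            raise ValueError("config needs a scenario or input CSVs")
        if "corn" not in self.unavailable.get(1, ()):
            raise ValueError(
                "Period 1 predates corn agriculture here; corn must be listed "
                "unavailable for period 1"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Build a config from a YAML file.

        Recognised sections: ``inputs`` (specimens csv + per-region sources
        csvs, or ``scenario`` options for the packaged generator), ``qc``
        (threshold overrides), ``grouping`` (k, n_perm, family_alpha),
        ``corrections`` (per-period d13C/d15N offsets), ``model`` (n_iter,
        burn_in, chains ...), ``periods`` (per-period unavailable sources)
        and a top-level ``seed``.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {"seed": int(raw.get("seed", 0))}
        inputs = raw.get("inputs", {})
        if "scenario" in inputs:
            from .simulate import paperlike_scenario

            opts = inputs["scenario"] or {}
            if opts.pop("name", "paperlike") != "paperlike":
                raise ValueError("only the 'paperlike' scenario is packaged")
            kwargs["scenario"] = paperlike_scenario(
                **opts, seed=int(raw.get("seed", 0)))
        else:
            kwargs["specimens_csv"] = inputs.get("specimens")
            kwargs["sources_csv"] = inputs.get("sources")
        if "qc" in raw:
            qc_raw = dict(raw["qc"])
            for key in ("cn_range", "cs_range", "ns_range", "pctS_range"):
                if key in qc_raw:
                    qc_raw[key] = tuple(qc_raw[key])
            kwargs["qc"] = QCThresholds(**qc_raw)
        grouping = raw.get("grouping", {})
        if "k" in grouping:
            kwargs["knn_k"] = int(grouping["k"])
        if "n_perm" in grouping:
            kwargs["knn_n_perm"] = int(grouping["n_perm"])
        if "family_alpha" in grouping:
            kwargs["family_alpha"] = float(grouping["family_alpha"])
        if "corrections" in raw:
            corr = raw["corrections"]
            kwargs["correction"] = CorrectionConfig(
                mode=corr.get("mode", "per_period_offsets"),
                d13C_offset={int(k): float(v)
                             for k, v in corr.get("d13C_offset", {}).items()}
                or {1: 1.6, 2: 0.3, 3: 0.0},
                d15N_offset={int(k): float(v)
                             for k, v in corr.get("d15N_offset", {}).items()},
            )
        if "model" in raw:
            kwargs["model"] = MixingModelConfig(
                **{k: v for k, v in raw["model"].items()},
                seed=int(raw.get("seed", 0)))
        if "periods" in raw and "unavailable" in raw["periods"]:
            kwargs["unavailable"] = {
                int(k): tuple(v)
                for k, v in raw["periods"]["unavailable"].items()}
        return cls(**kwargs)


@dataclass
class PipelineReport:
    qc_log: pd.DataFrame
    partitions: dict[str, dict]
    posteriors: dict[tuple[str, int], PosteriorResult]
    letters: dict[str, dict[str, dict[str, str]]]   # region -> source -> period -> letters
    tests: pd.DataFrame
    series: dict[tuple[str, str], BinnedSeries]
    change_points: dict[tuple[str, str], ChangePointResult]
    provenance: dict

    def summary_json(self) -> str:
        """Deterministic JSON summary (byte-identical across reruns per seed)."""
        out = {
            "provenance": self.provenance,
            "qc_excluded": sorted(self.qc_log["specimen_id"].unique().tolist()),
            "partitions": self.partitions,
            "posteriors": {
                f"{r}|P{p}": {
                    src: {
                        "mode": round(s["mode"], 6),
                        "mean": round(s["mean"], 6),
                        "hdr95": [[round(a, 6), round(b, 6)] for a, b in s["hdr95"]],
                    }
                    for src, s in res.summaries.items()
                }
                for (r, p), res in sorted(self.posteriors.items())
            },
            "letters": self.letters,
            "tests": self.tests.round(6).to_dict("records"),
            "change_points": {
                f"{r}|{ch}": {
                    "interval": cp.year_interval, "no_change": cp.no_change,
                }
                for (r, ch), cp in sorted(self.change_points.items())
            },
        }
        return json.dumps(out, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """QC → pooling → correction → fits → tests → series, with provenance."""
    config.validate()
    if config.scenario is not None:
        specimens, sources_by_region, _truth = generate_dataset(config.scenario)
    else:
        from .io import read_sources, read_specimens
        specimens = read_specimens(config.specimens_csv)
        sources_by_region = {
            region: read_sources(path) for region, path in (config.sources_csv or {}).items()
        }

    clean, qc_log = run_qc(specimens, config.qc)
    groups, _unassigned = split_by_period(clean, config.scheme)

    partitions: dict[str, dict] = {}
    pooled_by_region: dict[str, list[SourceGroup]] = {}
    seed_seq = np.random.SeedSequence(config.seed)
    region_seeds = {r: int(s.generate_state(1)[0] % 2**31)
                    for r, s in zip(sorted(sources_by_region),
                                    seed_seq.spawn(len(sources_by_region)))}
    for region in sorted(sources_by_region):
        tests = pairwise_source_tests(
            sources_by_region[region], family_alpha=config.family_alpha,
            k=config.knn_k, n_perm=config.knn_n_perm, seed=region_seeds[region],
        )
        partition, pooled = merge_sources(tests, sources_by_region[region])
        pooled_by_region[region] = pooled
        partitions[region] = {
            "mapping": partition.mapping,
            "alpha_adjusted": partition.alpha_adjusted,
            "n_tests": tests.n_tests,
            "p": {f"{a}|{b}": round(p, 6) for (a, b), p in sorted(partition.p.items())},
        }

    posteriors: dict[tuple[str, int], PosteriorResult] = {}
    fit_index = 0
    for (region, period), recs in sorted(groups.items()):
        pooled = pooled_by_region.get(region)
        if not pooled or len(recs) < 2:
            continue
        drop = set(config.unavailable.get(period, ()))
        avail = [g for g in pooled
                 if not any(cat in drop for cat in g.name.split("+"))]
        corrected = correct_sources_for_period(avail, period, config.correction)
        fit_cfg = MixingModelConfig(
            n_iter=config.model.n_iter, burn_in=config.model.burn_in,
            max_stored=config.model.max_stored,
            dirichlet_alpha=config.model.dirichlet_alpha,
            sigma_prior_upper=config.model.sigma_prior_upper,
            n_chains=config.model.n_chains,
            seed=(config.seed * 1000 + fit_index) % 2**31,
        )
        fit_index += 1
        posteriors[(region, period)] = fit_mixing_model(
            recs, corrected, config.tdf, fit_cfg
        )

    letters: dict[str, dict[str, dict[str, str]]] = {}
    for region in sorted({r for r, _ in posteriors}):
        period_results = {p: posteriors[(region, p)]
                          for r, p in sorted(posteriors) if r == region}
        src_names = sorted({s for res in period_results.values()
                            for s in res.source_names})
        letters[region] = {}
        for src in src_names:
            periods = [p for p, res in period_results.items()
                       if src in res.source_names]
            if len(periods) < 2:
                continue
            hdrs = [period_results[p].summaries[src]["hdr95"] for p in periods]
            lab = hdr_overlap_letters(hdrs, [f"P{p}" for p in periods])
            letters[region][src] = lab

    test_rows = []
    for region in sorted({r for r, _ in groups}):
        for channel in ("d13C", "d15N", "d34S"):
            by_period = {p: [getattr(r.isotopes, channel) for r in groups[(region, p)]]
                         for rr, p in sorted(groups) if rr == region
                         and len(groups[(region, p)]) > 0}
            vals = [v for v in by_period.values() if v]
            labels = [f"P{p}" for p, v in by_period.items() if v]
            if len(vals) < 2:
                continue
            kw = kruskal_wallis(vals, labels)
            test_rows.append({"region": region, "channel": channel,
                              "test": "kruskal_wallis", "groups": "|".join(labels),
                              "statistic": kw.statistic, "df": kw.df,
                              "p_value": kw.p_value})
            if len(vals) >= 3:
                for res in steel_dwass(vals, labels):
                    test_rows.append({"region": region, "channel": channel,
                                      "test": res.method,
                                      "groups": "|".join(res.groups),
                                      "statistic": res.statistic, "df": None,
                                      "p_value": res.p_value})
    tests_df = pd.DataFrame(
        test_rows, columns=["region", "channel", "test", "groups",
                            "statistic", "df", "p_value"])

    series: dict[tuple[str, str], BinnedSeries] = {}
    cps: dict[tuple[str, str], ChangePointResult] = {}
    for region in sorted({r.region.value for r in clean}):
        recs = [r for r in clean if r.region.value == region]
        for channel in ("d13C", "d15N", "d34S"):
            s = binned_series(recs, channel)
            series[(region, channel)] = s
            if len(s.table) >= 4:
                cps[(region, channel)] = change_point(s)

    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_iter": config.model.n_iter,
        "burn_in": config.model.burn_in,
        "knn_k": config.knn_k,
        "knn_n_perm": config.knn_n_perm,
        "family_alpha": config.family_alpha,
        "qc": {"cn": list(config.qc.cn_range), "cs": list(config.qc.cs_range),
               "ns": list(config.qc.ns_range), "pctS": list(config.qc.pctS_range)},
        "correction_mode": config.correction.mode,
        "d13C_offsets": {str(k): v for k, v in config.correction.d13C_offset.items()},
        "unavailable": {str(k): list(v) for k, v in config.unavailable.items()},
    }
    return PipelineReport(qc_log, partitions, posteriors, letters, tests_df,
                          series, cps, provenance)


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.qc_log.to_csv(out / "exclusions.csv", index=False)
    report.tests.to_csv(out / "tests.csv", index=False)
    (out / "summary.json").write_text(report.summary_json())
    for (region, channel), s in report.series.items():
        s.table.to_csv(out / f"series_{region}_{channel}.csv", index=False)
    for (region, period), res in report.posteriors.items():
        df = pd.DataFrame(res.p_flat, columns=list(res.source_names))
        df.to_csv(out / f"posterior_{region}_P{period}.csv", index=False)
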