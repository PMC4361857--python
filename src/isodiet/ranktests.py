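"""Nonparametric comparisons of isotope values across periods and subgroups.

Kruskal–Wallis (reported as "W" with g−1 degrees of freedom, as in the
source software's output convention), the Steel–Dwass all-pairs multiple
comparison, and the two-sample Wilcoxon rank-sum test.  Kruskal–Wallis and
Wilcoxon are delegated to scipy; Steel–Dwass is implemented here: for each
pair of groups, ranks are computed within that pair only, the rank-sum
statistic is standardized with the tie-corrected permutation variance, and
|t|·√2 is referred to the studentized-range distribution with g groups so
the pairwise p-values are jointly valid at familywise level without further
adjustment.  A permutation mode is available for small samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    method: str
    groups: tuple[str, ...]
    n: tuple[int, ...]
    df: int | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def kruskal_wallis(
    values: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H across ≥ 2 groups.

    The statistic is the classic midrank H with tie correction; p comes from
    the χ² distribution with df = g − 1.  All-identical data give H = 0,
    p = 1 (a case scipy refuses).
    """
    groups = [np.asarray(v, float) for v in values]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need >= 3 observations in total")
    labels = tuple(labels) if labels else tuple(str(i + 1) for i in range(len(groups)))
    pooled = np.concatenate(groups)
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, 1.0, "kruskal_wallis", labels,
                              tuple(len(g) for g in groups), df)
    h, p = stats.kruskal(*groups)
    return RankTestResult(float(h), float(p), "kruskal_wallis", labels,
                          tuple(len(g) for g in groups), df)


def _pair_rank_stat(x: np.ndarray, n1: int) -> tuple[float, float, float]:
    """(rank sum of first group, its null mean, tie-corrected null variance)."""
    n = len(x)
    n2 = n - n1
    r = stats.rankdata(x)
    w = float(r[:n1].sum())
    mean = n1 * (n + 1) / 2.0
    # permutation variance of the rank sum under ties:
    # Var(W) = n1*n2/(n*(n-1)) * (sum r^2 - n*(n+1)^2/4)
    var = n1 * n2 / (n * (n - 1)) * (float((r**2).sum()) - n * (n + 1) ** 2 / 4.0)
    return w, mean, var


def steel_dwass(
    values: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int | None = None,
) -> list[RankTestResult]:
    """Steel–Dwass all-pairs comparisons.

    asymptotic: q = |W − E| / sqrt(V) · √2 referred to the studentized-range
    distribution with k = number of groups and infinite df.
    permutation: within-pair permutation of the standardized statistic with
    the add-one p estimator (exhaustive when the pair is small enough),
    Bonferroni-free by construction only in the asymptotic sense — the
    permutation variant reports per-pair p-values labelled as such.
    """
    groups = [np.asarray(v, float) for v in values]
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    labels = tuple(labels) if labels else tuple(str(i + 1) for i in range(g))
    rng = np.random.default_rng(seed)
    out: list[RankTestResult] = []
    for i, j in itertools.combinations(range(g), 2):
        xi, xj = groups[i], groups[j]
        pooled = np.concatenate([xi, xj])
        n1 = len(xi)
        if np.all(pooled == pooled[0]):
            out.append(RankTestResult(0.0, 1.0, f"steel_dwass_{method}",
                                      (labels[i], labels[j]), (len(xi), len(xj))))
            continue
        w, mean, var = _pair_rank_stat(pooled, n1)
        t = (w - mean) / math.sqrt(var)
        if method == "asymptotic":
            q = abs(t) * math.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, g, np.inf))
        elif method == "permutation":
            n = len(pooled)
            n_distinct = math.comb(n, n1)
            if n_distinct <= n_perm:
                stats_null = []
                for combo in itertools.combinations(range(n), n1):
                    w0, m0, v0 = _pair_rank_stat_idx(pooled, np.array(combo))
                    stats_null.append(abs((w0 - m0) / math.sqrt(v0)) if v0 > 0 else 0.0)
                stats_null = np.array(stats_null)
                p = float((stats_null >= abs(t) - 1e-12).mean())
            else:
                count = 0
                for _ in range(n_perm):
                    idx = rng.permutation(n)[:n1]
                    w0, m0, v0 = _pair_rank_stat_idx(pooled, idx)
                    t0 = abs((w0 - m0) / math.sqrt(v0)) if v0 > 0 else 0.0
                    if t0 >= abs(t) - 1e-12:
                        count += 1
                p = (1 + count) / (1 + n_perm)
        else:
            raise ValueError(f"unknown method {method!r}")
        p = min(1.0, max(0.0, p))
        out.append(RankTestResult(float(t), p, f"steel_dwass_{method}",
                                  (labels[i], labels[j]), (len(xi), len(xj))))
    return out


def _pair_rank_stat_idx(pooled: np.ndarray, idx: np.ndarray) -> tuple[float, float, float]:
    n = len(pooled)
    n1 = len(idx)
    r = stats.rankdata(pooled)
    w = float(r[idx].sum())
    mean = n1 * (n + 1) / 2.0
    var = n1 * (n - n1) / (n * (n - 1)) * (float((r**2).sum()) - n * (n + 1) ** 2 / 4.0)
    return w, mean, var


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> RankTestResult:
    """Two-sided two-sample Wilcoxon (Mann–Whitney) rank-sum test.

    Exact null distribution when the combined sample has ≤ 20 observations
    and no ties; otherwise the normal approximation with continuity
    correction.  The variant used is recorded in ``method``.
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return RankTestResult(float(len(x) * len(y) / 2.0), 1.0,
                              "wilcoxon_exact", labels, (len(x), len(y)))
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 20 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "wilcoxon_exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        method = "wilcoxon_normal_approx"
    return RankTestResult(float(res.statistic), float(min(1.0, res.pvalue)),
                          method, labels, (len(x), len(y)))
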