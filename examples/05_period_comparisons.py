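"""Nonparametric tests of isotope change across historical periods.

Generates consumers for the three eastern periods and asks whether their
δ¹⁵N values differ: Kruskal–Wallis across all three periods (the omnibus
"W" statistic), then Steel–Dwass all-pairs comparisons that control the
familywise error without further adjustment, then a Wilcoxon check that
adult and non-adult bears do not differ (the study's control against
captive-feeding artefacts).
"""

import numpy as np

from isodiet import kruskal_wallis, steel_dwass, wilcoxon_rank_sum
from isodiet.simulate import generate_consumers, paperlike_scenario

scenario = paperlike_scenario(seed=3)
rng = np.random.default_rng(3)
by_period = {}
for period in (1, 2, 3):
    recs, _ = generate_consumers(scenario, "eastern", period, rng)
    by_period[period] = [r.isotopes.d15N for r in recs]

kw = kruskal_wallis(list(by_period.values()), [f"P{p}" for p in by_period])
print(f"Kruskal-Wallis: W = {kw.statistic:.3f}, {kw.df} df, "
      f"P = {kw.p_value:.3g}")
for res in steel_dwass(list(by_period.values()), [f"P{p}" for p in by_period]):
    print(f"  Steel-Dwass {res.groups[0]} vs {res.groups[1]}: "
          f"P = {res.p_value:.3g}")

half = len(by_period[1]) // 2
w = wilcoxon_rank_sum(by_period[1][:half], by_period[1][half:],
                      ("adults", "others"))
print(f"Wilcoxon within Period 1 (split halves, null case): "
      f"P = {w.p_value:.3f} ({w.method})")
# The trophic decline (animal-rich P1 -> plant-rich P3) shows up as a large
# W and significant pairwise drops in d15N; the within-period split is null.
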