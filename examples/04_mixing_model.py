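"""Fitting the concentration-dependent Bayesian mixing model.

Generates 30 consumers from known diet proportions (the packaged eastern
pre-development truth: terrestrial animals ~67%, salmon ~20%) and fits the
SIAR-style model by MCMC.  Printed posterior means land close to the
generating truth, and the 95% highest-density regions quantify what three
isotope channels can and cannot pin down.
"""

import numpy as np

from isodiet import (MixingModelConfig, SourceGroup,
                     correct_sources_for_period, fit_mixing_model)
from isodiet.simulate import (generate_consumers, generate_sources,
                              paperlike_scenario)

scenario = paperlike_scenario(seed=1)
rng = np.random.default_rng(1)
samples = generate_sources(scenario, "eastern", rng)
by_cat = {}
for s in samples:
    by_cat.setdefault(s.category, []).append(s)
groups = {c: SourceGroup.from_samples(c, ss) for c, ss in by_cat.items()}

period = 1
consumers, _ = generate_consumers(scenario, "eastern", period, rng)
truth = scenario.proportions[("eastern", period)]
available = [groups[c] for c in sorted(truth)]   # corn absent in Period 1
corrected = correct_sources_for_period(available, period, scenario.suess)

config = MixingModelConfig(n_iter=100_000, burn_in=20_000, seed=1)
result = fit_mixing_model(consumers, corrected, scenario.tdf, config)

print(f"{'source':>20s} {'truth':>6s} {'mean':>6s} {'mode':>6s}  95% HDR")
for name in result.source_names:
    s = result.summaries[name]
    lo, hi = s["hdr95"][0][0], s["hdr95"][-1][1]
    print(f"{name:>20s} {truth[name]:6.3f} {s['mean']:6.3f} "
          f"{s['mode']:6.3f}  [{lo:.3f}, {hi:.3f}]")
d = result.diagnostics
print(f"acceptance {d['acceptance_rate_p']:.2f}, "
      f"min ESS {d['ess_min']:.0f}, max split-Rhat {d['rhat_max']:.3f}")
# Posterior means sit within a few percentage points of the generating
# truth; the animal-dominated pre-development diet is clearly recovered.
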