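# Methods

This note documents the statistical machinery in `isodiet`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish.

## Data model

Isotope values are δ-notation per-mil deviations from international
standards (VPDB, AIR, VCDT), with the heavy/light convention ³⁴S/³²S used
throughout for sulfur. Missing channels are represented explicitly
(`None`), never imputed; every multi-record operation runs on the
intersection of channels present in all of its inputs. Atomic C:N, C:S and
N:S ratios are derived from weight percents with fixed atomic masses
(C 12.011, N 14.007, S 32.06) so values are bit-reproducible. The study
regions are a closed two-value enumeration (`western`, `eastern`); any
other label is a validation error rather than a silently accepted string.

## Collagen quality control

Pure-collagen windows (all closed intervals, all configurable):
atomic C:N ∈ [2.9, 3.6], atomic C:S ∈ [300, 900], atomic N:S ∈ [100, 300],
weight %S ∈ [0.15, 0.35]. Specimens with known age ≤ 2 years are excluded
(nursing signal in δ¹⁵N), as are specimens of unknown age unless bone size
marks them as clearly adult. A criterion whose inputs were never measured
(no %S on specimens without δ³⁴S) is recorded as *not evaluable* and does
not fail the record by default; the `require_sulfur_qc` switch inverts
that policy. The sulfur-bearing windows follow the standard collagen
convention of assigning [300, 900] to C:S and [100, 300] to N:S. QC is
idempotent and the exclusion log carries one row per failed criterion.

## Source distinguishability (KNN randomisation test)

Statistic: over all points of the pooled pair, the mean fraction of each
point's k Euclidean nearest neighbours (self excluded) sharing its
category label. Null distribution: random relabelings preserving group
sizes; p = (1 + #{perm ≥ obs}) / (1 + n_perm), the add-one estimator, so
p is never 0 and the test is exactly valid. An exact mode enumerates all
C(n, n_a) labelings for small groups. Choices the source text left open:

* **k = 3 by default** (stability over k = 1 while keeping locality),
  always recorded in the result.
* **Distances in raw ‰** over shared channels — no per-axis
  standardisation, keeping the metric interpretable; a `standardize` flag
  is available.
* Distance ties broken by stable point order; all-coincident inputs are
  flagged `degenerate`.

The family of all C(g, 2) pairwise tests is Bonferroni-adjusted
(α/m, so 0.005 at five categories; the threshold is always derived from
the actual pair count and logged). Categories connected transitively by
non-significant pairs are pooled; when the closure pulls in a pair that
individually tested significant, that pair is flagged in the partition.
A warning fires when n_perm is too small for any pair to reach the
adjusted threshold (minimum achievable p is 1/(n_perm+1)).

## Temporal (Suess) correction

Modern source means are shifted *up* onto the historical consumer's scale;
the modern period is the fixed point and δ³⁴S is never corrected. Two
modes:

* **Per-period offsets** (default): δ¹³C +1.6‰ for the pre-development
  period and +0.3‰ for the early-development period relative to the
  modern reference — the expected industrial-era δ¹³C declines for these
  period spacings. Optional δ¹⁵N offsets are capped at 0.4‰ in magnitude.
* **Reference curve**: a (year → atmospheric δ¹³C anomaly) table with
  linear interpolation, D(year) = anomaly(year) − anomaly(reference_year);
  no extrapolation outside coverage. The packaged default curve is a
  *stylized* rendering of the industrial-era decline (≈1.85‰ by 2020),
  intended for smoke tests; real analyses should supply a measured curve.

Corrections are mean shifts only: spreads ω and concentrations q are
untouched, so subtracting the same offset restores the input exactly.

## Mixing model

The concentration-dependent marginal-Gaussian mixing model (the published
SIAR structure, stated explicitly so the implementation is
self-contained): for consumer i and channel j,

    p′_jk = p_k q_jk / Σ_l p_l q_jl
    X_ij ~ Normal( Σ_k p′_jk (μ_jk + λ_j),  Σ_k p′_jk² (ω_jk² + τ_j²) + σ_j² )

priors Dirichlet(α=1) on p and Uniform(0, 20‰) on each residual SD σ_j
(both configurable). TDF defaults are the bone-collagen values
λ = (5.0, 3.0, 1.0)‰ and τ = (1.5, 1.5, 0.5)‰ for (δ¹³C, δ¹⁵N, δ³⁴S).

**Sampler.** Random-walk Metropolis on the additive-log-ratio transform of
p (Jacobian Σ log p_k included), with the proposal covariance learned from
the chain history during burn-in (Haario-style, scaled 2.38²/d, scalar
step tuned toward 30% acceptance) and per-channel scalar updates of σ_j.
All adaptation freezes at the end of burn-in, preserving detailed balance.
Defaults follow the study protocol — 1,000,000 iterations with the first
100,000 discarded — though the package's own tests use 100,000-iteration
runs, which the recovery checks show are already well converged for these
problem sizes. Two chains run by default (the original analysis reported
single runs; two chains cost little and enable split-R̂), stored draws are
thinned to ≤ 10,000 total (thinning factor recorded), and diagnostics
report acceptance rates, minimum effective sample size and maximum
split-R̂ (via arviz). A post-adaptation acceptance rate below 1% flags the
result as non-mixing instead of returning silently. Per-channel
log-likelihood terms are cached through sufficient statistics (Σx, Σx²),
so one iteration costs O(KJ) regardless of the number of consumers.

**Summaries.** Marginal mode = argmax of a Gaussian KDE (scipy's Silverman
bandwidth) on a 512-point grid over [0, 1]; HDRs are density-threshold
regions from the same KDE — grid cells admitted in decreasing density
order until the target mass is reached — which makes HDR(50) ⊆ HDR(75) ⊆
HDR(95) automatic and allows multi-interval regions. Group significance
letters are a greedy clique cover of the 95%-HDR overlap graph (maximal
cliques, ordered by earliest member), the usual compact-letter display.

**Identifiability.** With K sources and J channels the mean constraints
leave a (K−1−J)-dimensional flat set in the simplex; for the study design
(K = 5, J = 3) that is a line segment on which only the prior and the
(weak) variance structure act. Consequences: posterior means on 5-source
fits carry an irreducible design-dependent pull toward the segment
midpoint, and 4-source fits (pre-development period, corn absent) are
generically identified. The packaged scenario's source geometry was
chosen by minimizing an analytic proxy for this pull plus the linearized
noise amplification (see below).

## Nonparametric tests

* **Kruskal–Wallis** (scipy, midranks + tie correction), reported with the
  source convention's letter "W" and df = g − 1; all-identical data return
  H = 0, p = 1 rather than an error.
* **Steel–Dwass**: ranks computed within each pair only; rank-sum
  standardized by the tie-corrected permutation variance; |t|·√2 referred
  to the studentized-range distribution with g groups (asymptotic mode),
  giving jointly valid all-pairs p-values. The permutation mode enumerates
  all within-pair assignments when feasible (exact) and samples otherwise.
  Measured against exact enumeration, the asymptotic p overshoots by
  ≈ 0.026 at n = 4/group and ≈ 0.013 at n = 8/group on separated data —
  use the permutation mode for very small samples.
* **Wilcoxon rank-sum**: exact distribution when total n ≤ 20 with no
  ties, otherwise normal approximation with continuity correction; the
  variant used is recorded.

## Periods, series and change points

Region-specific strata: Period 1 ends 1890 (west) / 1920 (east); Period 2
is 1931–1942 and Period 3 starts 1996 in both regions. A specimen is
assigned only when its whole dated interval fits inside one bin; intervals
straddling a cutoff are left unassigned (conservative, logged) rather than
snapped to midpoints. Time-series bins are (site, year-interval) groups or
user-supplied edges — historical bin widths depend on archaeological
chronology the data must supply. The change-point readout is a
single-break piecewise-constant least squares on bin means weighted by bin
size, reporting the between-bin year interval and the SSE profile; it is a
numerical formalization of a judgement the original analysis made
visually, and reports flag it as such by carrying both the bins and the
fitted break.

## Synthetic-data generator

The generator is the exact forward model of the likelihood (same
concentration weighting, TDFs, variance structure), plus the field
realities the pipeline must survive: per-period δ¹³C drift matching the
correction defaults, instrument noise at the reported precisions
(0.1/0.3/0.5‰ for C/N/S), planted diagenetic failures (atomic C:N drawn
strictly outside [2.9, 3.6], ground-truth flagged) and nursing-age
animals. All randomness flows from one seed; reruns are bit-identical.

The packaged study-shaped scenario uses *synthetic* source values, not the
study's empirical ones: five categories with ≥ 3‰ separation on every
channel, plant/animal concentration contrasts (N ≈ 1–4% in plants vs
10–16% in animal tissue) that make the concentration weighting
consequential, ω = 0.4‰ within-category spread, residual σ = 0.2‰, 100
source samples per category and 30 consumers per period. Within those
realism constraints the means and concentrations were selected once, by
minimizing (i) the unidentified-segment midpoint offset at each period's
true diet and (ii) the linearized mapping of consumer/source-mean noise
into proportion error, so that recovery tests are decisive rather than
prior-dominated. True proportions follow the study's qualitative template
(eastern pre-development: animals ≈ 2/3, salmon ≈ 1/5; modern periods
plant-dominated; corn absent pre-development).

**What passing tests show — and don't.** Recovery within ±0.07
(seed-averaged over five generator seeds) demonstrates that the estimator
inverts its own forward model at the study's sample sizes and noise
levels. It does not certify accuracy on real collagen, where sources are
less separated, TDFs are themselves uncertain beyond the assumed τ, diets
vary across individuals, and source categories may be internally
heterogeneous — all of which widen (and can bias) real posteriors.

## Numerical conventions

* Proportions renormalised after the softmax so stored draws sum to 1
  within 1e−12.
* KDE of degenerate (zero-spread) draws returns the point value.
* Atomic-ratio division by zero yields a missing value, never an error.
* JSON summaries round to 6 decimals and sort keys, so a rerun with the
  same seed is byte-identical.
* Monte-Carlo p-values use add-one estimators; distance and density ties
  break by stable index order.

## Known limitations

* No isotope routing, no covariates inside the mixing model, no
  hierarchical pooling across periods or regions (each region × period is
  fitted independently, as the study reported them).
* The unidentified direction in 5-source/3-channel fits means posterior
  means are design-sensitive; report HDRs, not just point summaries.
* The asymptotic Steel–Dwass variant is anti-conservative below ~n = 8
  per group; the package offers the permutation mode for that regime.
* The default atmospheric δ¹³C curve is stylized, for tests only.
* Plot generation is out of scope; report tables carry the content of the
  figure-style outputs (HDR boxes, binned series).
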