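# isodiet

Millennium-scale diet reconstruction from bone-collagen stable isotopes.

Museum and archaeological bone collagen records what an animal ate over the
last years of its life: δ¹³C separates C₃ plants, C₄ plants (corn) and
marine prey, δ¹⁵N tracks trophic level, and δ³⁴S flags marine-derived
protein such as salmon. `isodiet` implements the full analysis chain used
to turn such measurements into diet histories for an omnivore sampled
across centuries — built around the case of brown bears whose salmon and
deer consumption collapsed after 19th-century development:

1. **Collagen quality control** — diagenetically altered specimens are
   excluded by atomic C:N ∈ [2.9, 3.6], C:S ∈ [300, 900], N:S ∈ [100, 300]
   and weight %S ∈ [0.15, 0.35]; nursing-age animals (≤ 2 yr) are dropped
   because milk inflates δ¹⁵N.
2. **Source distinguishability** — every pair of diet categories is
   compared with a K-nearest-neighbour randomisation test in δ-space;
   pairs that cannot be told apart at the Bonferroni-adjusted level
   (0.05/m for m pairs; 0.005 for the 5-category design) are pooled.
3. **Temporal (Suess) correction** — modern source δ¹³C is shifted onto
   each historical period's scale (defaults +1.6‰ and +0.3‰ for the
   pre-development and early-development periods relative to the modern
   one); δ³⁴S is never corrected.
4. **Concentration-dependent Bayesian mixing model** — a SIAR-equivalent
   model fitted by MCMC. With diet proportions p on the simplex and
   concentration weights p′ⱼₖ = pₖqⱼₖ / Σₗ pₗqⱼₗ, each consumer value is

   &nbsp;&nbsp;X<sub>ij</sub> ~ Normal( Σₖ p′ⱼₖ(μⱼₖ + λⱼ),
   Σₖ p′ⱼₖ²(ωⱼₖ² + τⱼ²) + σⱼ² )

   with trophic discrimination λ ± τ of 5.0 ± 1.5‰ (δ¹³C), 3.0 ± 1.5‰
   (δ¹⁵N), 1.0 ± 0.5‰ (δ³⁴S), a Dirichlet(1) prior on p and Uniform(0, 20‰)
   priors on the residual SDs σⱼ. Posteriors are summarised by KDE mode and
   50/75/95% highest-density regions, with compact-letter significance from
   95%-HDR overlap.
5. **Nonparametric period comparisons** — Kruskal–Wallis (the "W"
   statistic), Steel–Dwass all-pairs comparisons (asymptotic
   studentized-range or exact permutation), Wilcoxon rank-sum.
6. **Time series** — per-bin mean ± SD series and a piecewise-constant
   change-point readout of when the trophic decline began.

A synthetic-data generator (`isodiet.simulate`) reproduces the study's
design — 5 source categories, 2 regions × 3 periods, corn unavailable
pre-development, instrument noise 0.1/0.3/0.5‰ — with known ground truth,
so the whole pipeline is verifiable without the original specimens.

## Worked example

`examples/04_mixing_model.py` generates 30 consumers from a known
pre-development diet (terrestrial animals ~67%, salmon ~20%) and fits the
model with 100,000 iterations:

```
              source  truth   mean   mode  95% HDR
            C3_fruit  0.010  0.034  0.029  [0.000, 0.072]
             C3_herb  0.125  0.137  0.139  [0.102, 0.168]
              salmon  0.198  0.217  0.221  [0.180, 0.254]
  terrestrial_animal  0.667  0.612  0.613  [0.550, 0.675]
acceptance 0.30, min ESS 7107, max split-Rhat 1.000
```

Each row is one diet source: the generating truth, the posterior mean and
KDE mode of its dietary proportion, and the 95% highest-density region.
The animal-dominated diet is recovered within a few percentage points;
corn is absent because it did not exist in the pre-development period.
The other `examples/` scripts walk through QC, source pooling, the Suess
correction, the rank tests and the end-to-end pipeline; the `isodiet` CLI
(`isodiet simulate | qc | group-sources | compare | fit | pipeline`)
exposes the same stages from the shell.

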