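# vespine

Paternity analysis and phylogenetic comparative methods for social wasp
colonies (yellowjackets and hornets, subfamily Vespinae).

Queens of some vespine species mate with a single male while others use
sperm from up to half a dozen; why multiple paternity evolves is a
long-standing question in social insect biology. This package implements
the full analysis chain used to study that question from colony
microsatellite data:

1. **Patriline reconstruction** (`vespine.patrilines`): read worker (and
   optional queen) multilocus genotypes for single-queen haplodiploid
   colonies, filter workers with amplification failure, infer the queen
   genotype when she was not collected, and partition workers into the
   minimum number of patrilines consistent with one haploid father per
   group (deterministic branch-and-bound parsimony, with joint refinement of
   ambiguous queen loci against the partition).
2. **Paternity statistics** (`vespine.paternity_stats`): per colony of
   `n = Σ nᵢ` offspring with paternity shares `pᵢ = nᵢ/n`,
   - observed paternity `k` (number of patrilines),
   - effective paternity `kₑ = 1 / Σ pᵢ²`,
   - sample-size-corrected effective paternity
     `kₑ₃ = (n−1)² / [(Σ pᵢ²)(n+1)(n−2) + 3 − n]`,
   - intracolony relatedness `r = 1/4 + 1/(2 kₑ₃)`,
   - paternity skew (Nonacs B) `B = Σ(pᵢ − 1/k)² − (1 − 1/k)/n`,
   plus the male **non-detection error** (probability two fathers share a
   multilocus genotype, `Π_loci Σ_a f_a²`, with a conservative upper bound
   dropping the most variable ambiguous locus) and the **non-sampling
   correction** (inverting `E[k_obs] = k(1 − (1 − 1/k)ⁿ)`), aggregated into
   species summary tables (arithmetic mean k, harmonic mean kₑ/kₑ₃, 95% CIs).
3. **Comparative analysis** (`vespine.comparative`): phylogenetic
   generalized least squares with Pagel's λ — `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with
   `V = C(λ)`, the Brownian-motion covariance of the tree with off-diagonals
   scaled by λ; λ is profiled by maximum likelihood over [0, 1] with a
   χ²(1) likelihood-ratio 95% CI, and each model is refit at the
   conservative upper-CI λ. Effect sizes are `r = t/√(t² + df)` with
   Fisher-z CIs.
4. **Known-truth simulation** (`vespine.synthetic_data`): haplodiploid
   colony genotypes (Hardy–Weinberg queen, haploid fathers, Dirichlet
   paternity shares, missing calls) and species trait data under the PGLS
   generative model, so every stage can be validated against simulated
   truth.

A command-line pipeline (`vespine simulate | paternity | pgls | pipeline`)
wraps the library, and the numbered scripts under `analysis/` run the study
end to end on simulated data.

## Worked example

```sh
python analysis/01_simulate_dataset.py     # 5 species x 10 colonies + traits/tree
python analysis/02_paternity_analysis.py   # patrilines and paternity statistics
python analysis/03_comparative_pgls.py     # PGLS model suite
python analysis/04_estimator_validation.py # Monte-Carlo estimator checks
```

The paternity step prints the species summary (here on the default
simulated dataset, truth `k` = 2/2/3/3/4):

```
    species  n_c  k_mean    k_e   k_e3  B_mean  k_true_expected  nondetection
    acadica   10     2.0 1.5974 1.6437  0.1010           2.0000           0.0
 atropilosa   10     1.9 1.4870 1.5219  0.1111           1.9000           0.0
 consobrina   10     2.8 2.1954 2.3263  0.0572           2.8007           0.0
flavopilosa   10     4.0 2.8409 3.1106  0.0645           4.0130           0.0
      vidua   10     2.8 2.1692 2.2956  0.0627           2.8007           0.0

colonies where observed k equals simulated truth: 100.0%
```

`k_mean` is the arithmetic mean number of detected patrilines per colony;
`k_e`/`k_e3` are harmonic-mean effective paternities (the corrected value is
slightly larger, as expected at 20 offspring per colony); `B_mean` is the
average skew over multiple-paternity colonies; `k_true_expected` is the
non-sampling-corrected paternity, which stays essentially equal to `k_mean`
at these sample sizes; and the non-detection error is negligible (~1e-5) on
a six-locus panel. The comparative step then reports, per model and λ
setting, coefficients, t, p and effect sizes, e.g.

```
model                                   lambda  predictor    estimate     t      p
relatedness ~ log10(size) + nest_site   0.60    log10(size)  -0.0707  -2.96  0.008
```

i.e. species with larger colonies have lower intracolony relatedness on the
simulated data, mirroring the pattern the method is designed to detect.

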