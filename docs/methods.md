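# Methods

## The inference problem

Vespine wasps are haplodiploid: queens are diploid, males haploid. Every
daughter of a singly-queened colony carries one of her mother's two alleles
and her father's single allele at each locus, so the offspring of one father
(a *patriline*) share a paternal allele at every locus. Given multilocus
microsatellite genotypes for ~20 workers per colony, the analysis
reconstructs patrilines, quantifies paternity and its skew, and asks — with
phylogenetically controlled regressions across species — whether colony size
and nest site predict paternity traits.

## Patriline reconstruction

**Filtering.** Workers failing to amplify at more than two loci are excluded
(`max_failed_loci = 2`, configurable). A locus with any uncalled allele is
treated as missing for that individual.

**Queen inference.** When the queen was genotyped her genotype is used
directly. Otherwise, per locus, every diploid genotype over the alleles
observed in workers is scored by the number of workers carrying at least one
candidate allele (missing loci always compatible); candidates compatible
with the most workers are retained. If several candidates tie, the tie is
provisionally broken by the product of population allele frequencies and the
locus is flagged ambiguous — but the final choice is made *jointly with the
partition* (below). A colony in which no candidate is compatible with all
workers at two or more loci is rejected as structurally inconsistent with a
single queen (multi-queen or mixed sample).

**Why joint refinement is necessary.** Per-locus worker compatibility cannot
always identify the queen. Two failure modes recur in simulation: (i) if all
fathers share an allele at a locus, a homozygous candidate for that allele
ties the true queen on compatibility; (ii) for a homozygous queen, the
"flipped" reading (maternal allele reinterpreted as a single shared paternal
allele) is equally or more compatible. A wrong choice of type (i) reads
maternal alleles as paternal and splinters true patrilines; type (ii) is
usually harmless (it merely makes the locus uninformative). Joint inference
resolves both: for each ambiguous locus, each tied candidate is evaluated by
the partition it induces, and the candidate minimising (father count,
excluded workers, flagged workers, frequency rank) is kept, by deterministic
coordinate descent (two passes; one suffices in practice). This mirrors
likelihood-based sibship software, which infers parental genotypes and
sibship structure in one model, while remaining deterministic. With this
refinement, simulated queenless colonies (20 workers, 6 loci of ~8 alleles,
k = 3) are reconstructed exactly in 300/300 trials.

**Paternal alleles and partition.** For each worker and locus: one
non-maternal allele forces the paternal allele; two maternal alleles leave a
two-allele ambiguity set; missing loci are wildcards. A worker maternally
incompatible (no shared allele) at ≥2 loci is excluded as a foreign-matriline
intruder; a single incompatible locus — a possible mutation, null allele or
scoring error — is masked and the worker flagged but retained. The partition
minimises the number of fathers such that each group's per-locus paternal
sets intersect. Exact search uses iterative-deepening DFS with groups tried
in creation order, which returns the lexicographically first minimal
assignment over workers sorted by id (fully deterministic); it is applied up
to 25 workers, beyond which a greedy first-fit plus pairwise-merge heuristic
is used and the result marked not provably minimal. Exactness is verified
against brute-force enumeration of all set partitions on colonies of ≤8
workers.

**Allele frequencies** are estimated from inferred parental genomes — two
copies per queen, one per reconstructed father (ambiguous or wildcard loci
skipped) — rather than from raw workers, which would double-count large
patrilines. Expected heterozygosity is `H = 1 − Σ f²`.

## Paternity statistics

For patriline counts `n_i`, `n = Σ n_i`, `p_i = n_i/n`:

* `k_e = 1/Σ p_i²` — effective paternity, the equivalent number of equally
  contributing fathers.
* `k_e3 = (n−1)² / [(Σ p_i²)(n+1)(n−2) + 3 − n]` — a finite-sample
  correction of `k_e`. It satisfies `k_e3 = 1` exactly for a single father,
  `k_e3 ≥ k_e` for n ≥ 3, and converges to the true effective paternity as
  n → ∞ (checked to 1e-3 at n = 3·10⁴); relative bias is ≤ ~3% at n = 20
  over k ∈ 1..6 and Dirichlet(α ≥ 1) shares.
* `r = 1/4 + 1/(2 k_e3)` — expected worker–worker relatedness in a
  singly-queened haplodiploid colony (3/4 for full sisters, → 1/4 as
  paternity grows).
* `B = Σ (p_i − 1/k)² − (1 − 1/k)/n` — skew corrected for multinomial
  sampling noise, so `E[B] = 0` under equal expected shares (may be
  negative); defined only for k ≥ 2 and averaged over multiple-paternity
  colonies. When true k is large relative to n, unsampled patrilines shrink
  the observed k and displace mean B slightly (≈ −0.02 at k = 4, n = 10);
  at the study's n ≈ 20 and k ≤ 4 the displacement is within Monte-Carlo
  error of zero.

**Non-detection error** — the chance two fathers share a full multilocus
genotype and are merged — is `Π_loci Σ_a f_a²` for haploid males. Because an
ambiguous queen locus weakens this guarantee, a conservative upper bound
recomputes the product with the single most variable ambiguous locus
removed.

**Non-sampling correction.** Under even sperm use the expected number of
*detected* patrilines is `E[k_obs] = k(1 − (1 − 1/k)ⁿ)`. The correction
inverts this increasing map by bisection (1e-8) to give the expected true
paternity; `k_obs = 1` maps to 1 exactly and `k_obs = n` is unidentifiable
(reported infinite with a warning). The inverse direction is fixed by the
requirement that corrected values are ≥ observed means.

**Species aggregation.** Observed paternity k: arithmetic mean ± 1.96·SE.
Effective paternities: harmonic means, with CIs formed on the reciprocal
scale (normal CI of the mean of 1/k_e, endpoints inverted) — the convention
recovered from the symmetric reciprocal-scale intervals of published
species tables; a t-quantile CI would not reproduce that symmetry.

## Comparative analysis (PGLS with Pagel's λ)

Species values are correlated through shared ancestry. Under Brownian
motion the residual covariance of tips i, j is proportional to their shared
root-to-MRCA branch length `C[i,j]` (computed from patristic distances as
`(d(root,i)+d(root,j)−d(i,j))/2` and cross-checked against explicit
root-path enumeration). Pagel's λ multiplies the off-diagonal of C: λ = 0
is ordinary least squares (star phylogeny), λ = 1 is Felsenstein's
independent contrasts (verified against a hand-computed three-tip
contrast).

Fitting: GLS through a Cholesky whitening, `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with
`V = C(λ)`. Two variance conventions are used deliberately: the ML variance
`RSS/n` inside the λ profile likelihood, and the unbiased `RSS/(n−p)` for
standard errors and t tests (df = n − p, two-sided) — the pairing needed to
mimic standard comparative-methods output. λ is profiled on a 101-point
grid over [0, 1] with bounded refinement to 1e-4; the 95% CI is the
deviance set `2(ℓ_max − ℓ(λ)) ≤ 3.841`, an endpoint reported as "na" when
the deviance never reaches the cutoff before the boundary. Conservative
refits use the upper CI λ, substituting λ = 1 when that bound is "na". A
flat profile (range < 1e-8) returns λ = 0 with a warning.

Model suite: relatedness, paternity frequency and inverse skew each on
log₁₀(colony size) + nest-site fraction, plus relatedness on k + B⁻¹; a
variant of the skew model without nest site; mean vs maximum colony size;
any alternate tree. Transforms: log₁₀ for colony size, reciprocal for B
(both to improve homoscedasticity); complete-case deletion per model;
nest-site fraction treated as a continuous covariate in [0, 1]. Effect
sizes: `r = sign(t)·√(t²/(t²+df))` with Fisher-z CIs using SE `1/√(df−3)`
(undefined for df ≤ 3) — the convention that reproduces published intervals
from their t and df. A residual location/scale/shape summary (including a
Shapiro–Wilk p) is written with every report so residual normality can be
reviewed; it is reported, not auto-judged.

## Synthetic data

`simulate_colony` draws the queen's two allele copies per locus from the
panel frequencies (Hardy–Weinberg), each father as a haploid draw, and each
worker as a uniform maternal allele plus its father's allele, with the
father drawn from the share vector (fixed, or symmetric Dirichlet with
configurable α so skew is tunable) and independent per-locus missingness.
Defaults mirror the study's design: ~20 workers per colony, 10 colonies per
species, 6 loci with ~8-allele Dirichlet(5) frequency spectra, 2% missing
calls. Draw order is documented and a single seeded stream drives each
dataset, so outputs are bit-identical across runs. There is no linkage,
mutation or mistyping — only missingness — matching what the analysis
assumes; genotyping error robustness is therefore *not* demonstrated by
these simulations beyond the single-locus-mismatch tolerance.

`simulate_traits` draws `y = Xβ + ε`, `ε ~ MVN(0, σ²·C(λ_true))`, by
Cholesky factorisation. The bundled comparative dataset generates log
colony sizes ~10²–10⁴ workers and Beta(0.5, 0.5) nest-site fractions,
drawn independently across species; real nest-site habit is phylogenetically
conserved, so simulated predictors are less structured than real ones.
Trees come from a seeded sequential-join process rescaled to unit depth —
a stand-in for a rate-smoothed molecular phylogeny, without calibrated
node ages.

## Numerical and design notes

* Problem sizes in tests and the acceptance script (200 oracle colonies,
  10⁴ skew draws, 500 PGLS replicates, 1000 end-to-end recoveries) were
  chosen to make Monte-Carlo standard errors small relative to the effects
  checked.
* ML λ̂ at n = 22 is noisy and downward-biased: at λ_true = 0.5 the
  estimate piles up on both boundaries (roughly 40% at 0, 30% at 1) and its
  mean across random trees spans ~0.26–0.48. Consequently p-values from
  fits at the estimated λ are anticonservative at this sample size (about
  24% of null p < 0.05); the t test is exactly calibrated when V is correct,
  so calibration checks are run at the generating λ. Conservative upper-CI
  refits exist precisely to blunt this in the real analysis.
* Ties in queen inference are resolved deterministically (frequency product,
  then numeric order) and the partition search returns the lexicographically
  first minimal solution, so all outputs are reproducible byte-for-byte.
* Degenerate inputs: empty retained worker sets are allowed and flagged
  downstream; single-colony species get NaN CIs; a constant predictor
  raises a rank error rather than silently dropping a column; non-PSD
  covariances raise a decomposition error.

## Known limitations

* The partitioner is a parsimony method: it reports the minimum father
  count consistent with the data, not a likelihood-weighted estimate, and
  cannot model genotyping error rates or null alleles beyond the
  single-locus tolerance. With informative panels (here, pairwise father
  collision probability < 1e-4) it matches simulated truth essentially
  always, but low-diversity panels would understate paternity.
* Multi-queen colonies and diploid males are out of scope; such colonies
  are rejected rather than modelled.
* The combinatorial queen-ambiguity flag is not a posterior probability;
  it marks loci where several genotypes explain the workers equally well.
* Passing simulation tests demonstrates correctness of the estimators under
  the generative assumptions (no linkage, independent loci, single queen),
  not robustness to real-data artefacts such as allele dropout or scoring
  drift.
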