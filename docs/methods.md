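# Methods

This note documents the models, estimators and numerical choices behind
`contactzone`, and what the synthetic study design does and does not show
about real data.

## The question the pipeline asks

Two binary partitions of a transect's sites compete to explain nuclear
genetic structure: the **allopatric** partition (which historical lineage —
precursor island — a site belongs to, proxied by its modal mtDNA lineage)
and the **ecological** partition (which side of a habitat transition the
site lies on). If reproductive isolation evolved in allopatry, nuclear
clusters should match the lineage partition; if isolation by adaptation
dominates, they should match the habitat partition. The pipeline quantifies
each fit with φ = √(χ²/n) on the 2×2 cluster-by-category table, and
corroborates with hierarchical AMOVA (Φ_CT under each grouping) and mean
standardized differentiation (F_ST′) across each boundary.

## Synthetic transects

The generator is phenomenological: it draws data directly from the cline
structure the analysis is designed to detect, rather than simulating
demography forward in time. This gives exact, interpretable ground truth
for acceptance checks at desk scale.

- **Lineage divergence.** Per locus, two lineage allele-frequency vectors
  are drawn around a common ancestral Dirichlet(1) vector via a
  Balding–Nichols draw with concentration (1−F)/F. F ∈ [0,1) is the single
  divergence knob; expected heterozygosity decreases in F.
- **Nuclear ancestry.** Site mean ancestry follows a logistic cline
  μ(x) = 1/(1+exp((x−c)/w)) in site units; individual ancestry is
  Beta(μτ, (1−μ)τ) with concentration τ (default 20 — individuals scatter
  realistically about their site mean; τ→∞ gives hard population blocks).
  Each allele copy independently originates from lineage 1 with probability
  q. mtDNA lineage is a Bernoulli draw from an *independent* logistic
  cline, so cyto-nuclear discordance (the phenomenon of interest) is a
  direct parameter: set c_mt ≠ c_nuc.
- **Sampling design.** Defaults mirror the field design the pipeline
  targets: 48 genotyped individuals per site at 9 multiallelic loci
  (8 alleles per locus by default), 10 trait-measured adult males per site,
  5–9 sites per transect depending on preset.
- **Climate.** The 19 bioclimatic variables are generated as
  baseline × exp(loading·f(x) + ε), where f(x) is a latent habitat factor
  (flat, linear gradient, or step at the ecotone) and ε is ln-scale noise
  (default SD 0.05–0.08). Precipitation loads positively, temperature
  weakly negatively (wetter and cooler uphill). The multiplicative form
  guarantees positive values and makes the analysis-side ln transform
  recover a linear factor structure.
- **Traits.** 27 columns (21 morphology-like, 6 hue-like) respond linearly
  to the habitat factor (β per block) and to the individual's mtDNA lineage
  (δ per block), with unit residual SD so effects read directly in
  within-group SD units.
- **Presets.** `coastal_contact` (steep co-located nuclear/mtDNA clines at
  the geological boundary, flat climate, strong trait-lineage effect),
  `rainforest_ecotone` (nuclear cline centered on a 7-site climate step at
  3.5, mtDNA boundary at 5.5, habitat-driven traits), `mesic_contact`
  (shallow nuclear cline, gentle gradient), `control` (no clines, F = 0.02).
  Trait effect sizes were set so canonical-variate magnitudes land in the
  10–20 within-group-SD range typical of strongly differentiated ecotypes.

What the generator does **not** emulate: linkage and microsatellite
mutation processes, isolation by distance within lineages, selection
through time, spatially autocorrelated climate noise, measurement error in
traits. Passing tests therefore demonstrate correctness of the estimators
and the logic of the comparative framework under the assumed cline
structure — not robustness to every feature of real field data.

## Estimators and numerical choices

**Admixture clustering.** Gibbs sampler over the latent cluster of every
allele copy; conditionals: P ~ Dirichlet(λ + counts) per cluster × locus
(λ = 1), Q ~ Dirichlet(α + counts) per individual, α by Metropolis random
walk (step SD 0.25) under a uniform prior on (0, 10]. Missing allele copies
enter no counts and no likelihood. Q and P are posterior means over thinned
post-burn-in samples (thin 10); lnP(D) = mean − var/2 of the complete-data
log-likelihood over the same samples (sample variance, n−1). Desk-scale
default is 2 000 burn-in / 8 000 iterations with 3 replicates over
K ∈ {1,2,3}; `PAPER_SCALE` exposes 100 000 / 400 000 × 10 over K ∈ 1..9.
K selection takes the maximal mean lnP(D); when the top two means differ by
less than one pooled replicate SD the smaller K wins and a tie is flagged.
Replicate runs are aligned by the cluster permutation maximizing summed
column-wise correlation with the first run (solved exactly as an assignment
problem). Hard assignments take the argmax of the aligned mean Q, ties to
the lower cluster index. Dirichlet draws are floored at 1e−300 to avoid
underflow to an exact zero when α is small.

**AMOVA.** Mismatch (infinite-allele) distance between allele copies;
sums of squares per locus from allele counts (SS of a set = (n − Σc²/n)/2,
algebraically identical to the pairwise-distance form), standard
unbalanced-design coefficients, variance components summed over loci.
Φ_CT significance: whole populations permuted among groups (group sizes in
populations preserved), p with +1/+1 correction, default 9 999
permutations. Negative components are retained in the Φ report. The
repeat-size (R_ST-style) distance is deliberately not used — the framework
reports F_ST-type statistics.

**F_ST and F_ST′.** Multilocus Weir–Cockerham θ, variance components
summed over alleles and loci before the ratio; individuals missing a copy
at a locus are dropped at that locus. F_ST′ = θ/θ_max, with θ_max computed
after recoding alleles so no two populations share any allele (this
preserves within-population genotype structure and heterozygosity exactly
and maximizes between-population differentiation given within diversity).
Negative θ is reported raw; F_ST′ is truncated at 0. The boundary summary
averages F_ST′ over all cross-boundary site pairs and keeps within-block
pairs as a control.

**Climate PCA and the ecotone.** Variables are ln(x+s)-transformed (s = 1
only for columns containing zeros) and column-standardized — the variables
mix °C and mm, so correlation-matrix PCA is the defensible default. The
"trend" component is chosen by maximal |r| with transect position, not by
rank, and its sign is oriented positive with position. The ecotone
cut-point is (max+min)/2 of the trend scores. Because a midpoint split
exists even for pure noise, `analyze_transect` treats a transect as
crossing an ecotone only when told so (`has_ecotone`) or when the trend is
simultaneously large (score range ≥ 3), dominant (≥ 50% of variance) and
position-tracking (|r| ≥ 0.7); these thresholds are configurable and were
chosen from the generative model's score scale.

**Canonical variates.** Sites are the groups. The leading axis solves the
generalized eigenproblem S_b v = λ S_w v; scores are scaled so the pooled
within-group SD is exactly 1 and the axis sign makes site means increase
with position. A singular pooled within-group covariance is
ridge-regularized (λ = 1e−6 · trace/p) with a warning. Heteroscedasticity
is flagged by the spread of per-site log total variance (max − min of
ln tr(S_i); threshold 2.5): full per-site covariance determinants are
singular at 10 individuals × 27 traits, so a Box's-M-style determinant
comparison is not available at this design. Above threshold the method
falls back to PCA of standardized site means (`pca_site_means` tag).
Missing trait cells are imputed by the site mean and counted.

**φ tests.** Pearson χ² without continuity correction (the target sample
sizes, n ≈ 240–420, make the correction negligible), φ = √(χ²/n),
asymptotic 1-df p. Tables with a zero marginal return a degenerate result
rather than raising. Modal-lineage ties exclude the site's individuals
(conservative, logged). When the selected K ≠ 2, the comparative φ uses a
forced K = 2 run and is flagged. φ p-values are reported per test without
family-wise adjustment; a Bonferroni helper is provided.

**HWE / LD checks.** HWE: the absolute deviation of the heterozygote count
from its random-pairing expectation, against ≥ 10 000 seeded re-pairings of
the observed allele pool; monomorphic loci return p = 1 with a flag. LD:
Pearson χ² of the genotype-category contingency table against permutations
of one locus across individuals. Both statistics are discrete, so their
permutation p-values are slightly conservative at small samples; the null
calibration runs use large samples (HWE: 1 600 individuals) so the
discreteness is negligible relative to the KS resolution at 1 000
replicates.

## Problem sizes

Simulation-backed checks run at the generator's default design (48/site,
9 loci) with the desk-scale MCMC settings above; scenario contrasts use 20
replicate seeds per preset, estimator-consistency checks 20–50 seeds, and
exhaustive oracles cover all 2×2 tables with n ≤ 40 and all population
permutations of ≤ 12-individual AMOVA fixtures.

## Known limitations

- The admixture sampler implements the uncorrelated-frequencies prior
  only (no F-model, no linkage, no spatial prior), and convergence is
  monitored only through the log-likelihood trace summary.
- The ecotone rule assumes a single transition; multiple boundary
  crossings are flagged but only the first is reported.
- AMOVA assumes the mismatch distance; Φ values are not comparable to
  repeat-size-based R_ST analyses.
- The φ framework is strictly binary (two clusters, two categories);
  transects spanning three lineages must be analyzed pairwise.
- Cline-shape fitting (maximum-likelihood center/width estimation) is out
  of scope; `cline_center` offers only linear interpolation of the 0.5
  crossing for diagnostics.
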