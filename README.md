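# contactzone

Population-genetic tests of **allopatric vs. ecological speciation** along
geographic transects, built for study systems like the Lesser Antillean
anoles: formerly separate island lineages now meeting in secondary contact
zones on a single island that is also crossed by a sharp habitat transition
(a xeric-coast / montane-rainforest ecotone).

The package is aimed at population geneticists who want a self-contained,
scriptable re-implementation of the classic transect workflow:

- **mtDNA lineage assignment** by in-silico PCR-RFLP: digest a cytochrome-*b*
  amplicon with SspI / DraI motifs and classify each individual by the cut
  pattern (uncut → central; cut ≈ 598 → south; cut ≈ 166 then DraI ≈ 227 →
  northwest, DraI uncut → southwest).
- **Habitat characterization**: PCA of the ln-transformed 19-variable
  bioclimate profile per site; the component most correlated with transect
  position is the climatic trend, and an ecotone cut-point is the midpoint
  between its extreme site scores.
- **Quantitative traits**: canonical variate analysis with sites as groups,
  scores scaled to unit pooled within-group SD (with a PCA-of-site-means
  fallback when within-site dispersions are too unequal).
- **Nuclear structure**: an admixture-model Gibbs sampler for multiallelic
  genotypes (memberships *q*, cluster allele frequencies *P*, Dirichlet
  parameter α), model size chosen by the evidence approximation
  lnP(D) = mean(lnL) − var(lnL)/2 over replicate runs; allele-frequency PCA;
  Monte-Carlo exact-style HWE and linkage-disequilibrium checks.
- **Differentiation**: hierarchical AMOVA (mismatch distance, Φ-statistics,
  permutation test for Φ_CT) and pairwise Weir–Cockerham θ standardized by
  its maximum (F_ST′ = θ/θ_max via population-unique allele recoding).
- **Speciation tests**: the φ = √(χ²/n) goodness of fit between genetic
  clusters and the binary categories each speciation model predicts —
  modal mtDNA lineage per site (allopatric), habitat side of the ecotone
  (ecological), or the geological boundary.

Because the original field data are not public, a **synthetic transect
generator** with retained ground truth (logistic nuclear and mtDNA clines,
Balding–Nichols lineage divergence, latent-factor climate, habitat- and
lineage-driven traits) stands in for them; every downstream stage is tested
against it and against independent oracles.

## Worked example

```python
import contactzone as cz

params = cz.scenario_preset("rainforest_ecotone")   # nuclear cline on the
ds, truth = cz.simulate_transect(params, seed=3)    # ecotone, mtDNA apart

cfg = cz.AnalysisConfig(
    mcmc=cz.McmcConfig(k_range=(1, 2), n_replicates=2, seed=3),
    geological_boundary=params.geological_boundary,
)
rep = cz.analyze_transect(ds, cfg, seed=3)
print("chosen K:", rep.k_selection["chosen_k"])
print("phi allopatric:", round(rep.phi_allopatric["phi"], 2),
      " phi ecological:", round(rep.phi_ecological["phi"], 2))
print("AMOVA lineage  Phi_CT %.4f p %.3f" % (
    rep.amova_lineage["phi_ct"], rep.amova_lineage["p_phi_ct"]))
print("AMOVA habitat  Phi_CT %.4f p %.3f" % (
    rep.amova_habitat["phi_ct"], rep.amova_habitat["p_phi_ct"]))
print("mean F_ST' lineage %.3f habitat %.3f" % (
    rep.fst_lineage["mean_fst_std"], rep.fst_habitat["mean_fst_std"]))
```

Output (seed 3):

```
chosen K: 2
phi allopatric: 0.55  phi ecological: 0.96
AMOVA lineage  Phi_CT 0.0546 p 0.181
AMOVA habitat  Phi_CT 0.1721 p 0.026
mean F_ST' lineage 0.304 habitat 0.460
```

Reading: the two nuclear clusters track the **habitat** boundary, not the
old lineage boundary — the ecological model fits far better (φ 0.96 vs
0.55), among-habitat structure is significant while among-lineage structure
is not, and standardized differentiation across the ecotone exceeds that
across the lineage contact. That is the signature of isolation by
adaptation overriding a signature of past allopatry.

A CLI mirrors the library (`contactzone simulate|digest|assign-lineage|
climate|traits|structure-run|amova|fst|analyze`).

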