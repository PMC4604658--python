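# nichephylo

Multi-scale ecological coherence and dual-marker phylogenetic congruence
analysis for soil microbial amplicon surveys.

Soil Thaumarchaeota — the archaeal phylum containing the ammonia-oxidising
archaea (AOA) — are routinely surveyed with two marker genes: the 16S rRNA
gene and the fast-evolving functional gene *amoA* (ammonia monooxygenase
subunit A). Two questions recur in this literature. First, *ecological
coherence*: do phylogenetic lineages share environmental preferences (above
all soil pH) that distinguish them from other lineages, and at which
taxonomic resolution does each environmental factor matter? Second,
*phylogenetic congruence*: do the trees inferred from the two markers agree,
as expected when horizontal transfer between lineages is rare? `nichephylo`
implements the full analysis pipeline for both questions, plus a synthetic
dual-marker study generator with known truth so every stage is testable
without sequence downloads.

## What the pipeline computes

1. **Multi-scale OTU clustering.** Abundance-ordered greedy centroid
   clustering of dereplicated reads at the identity ladder
   100/97/95/90/85/80/70%, with per-soil relative-abundance matrices
   (soils below a read floor are excluded, mirroring survey practice).
2. **Coherence table.** For every environmental factor `x`, threshold and
   data set (all-16S, AOA-only 16S, *amoA*), a canonical correspondence
   analysis (CCA) of the soils-by-clusters table `Y` constrained on `x`
   alone. CCA follows ter Braak: with `P = Y / y..`, row and column masses
   `r`, `c`, the chi-square residuals `Q̄ = (P − rcᵀ)/√(rcᵀ)` are projected
   onto the constraint with row weights `r`; the constrained eigenvalues are
   the squared singular values of the projection. Significance is a
   permutation test of the pseudo-F
   `F = (inertia_constrained/q) / (inertia_residual/(n−q−1))`, with
   `p = (#{F* ≥ F} + 1)/(nperm + 1)`. Spearman rank correlations between
   factors accompany the table.
3. **Trees with supports.** Neighbor-joining on JC69-corrected distances
   with bootstrap supports in [0, 1] (same structure as posterior supports),
   patristic distance matrices, and principal coordinates (PCoA).
4. **Phylogenetic cluster delineation.** Maximal clades whose tips all
   exceed 90% pairwise identity and whose root support exceeds 0.70; each
   cluster gets abundance-weighted environmental preferences, a pH class
   (acidophilic < 5.5 ≤ neutrophilic ≤ 7.0 < alkalinophilic), and a
   polynomial pH-response curve chosen by AICc.
5. **Ancestral states.** Maximum-likelihood Brownian-motion reconstruction
   of habitat preferences (pH, water content, organic matter, nitrate
   proportion) at every internal node, by a linear-time two-pass algorithm
   equivalent to generalised least squares: root state
   `(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x`, internal nodes by re-rooting, `σ̂² = xcᵀV⁻¹xc/n`.
6. **Congruence.** A two-tier cross-marker cluster correspondence matrix
   (reference-anchored links, then suggested links between abundant clusters
   with similar read fraction and pH preference), and the global ParaFit
   statistic `trace(DᵀD)` with `D = Cᵀ A B`, where `B`, `C` are principal
   coordinates of the two patristic matrices and `A` the 0/1 association
   matrix; its null permutes the row order of `A`.

## Worked example

Simulate a study at the survey's own scale (46 soils over pH 3.5–8.5,
10,000 reads per soil, 32 taxa), cluster the *amoA* reads across the
threshold ladder, and test pH at every scale:

```python
from nichephylo import (SimulationConfig, simulate_study, multiscale_cluster,
                        relative_abundance_matrix, permutation_test_factor)

cfg = SimulationConfig(n_taxa=32, n_soils=46, depth=10_000, seed=1)
study = simulate_study(cfg)
ladder = multiscale_cluster(study.records_amoA)
for t, cs in sorted(ladder.items(), reverse=True):
    mat = relative_abundance_matrix(cs, study.records_amoA, 1000)
    p = permutation_test_factor(mat, study.truth.env.factor("pH"),
                                nperm=999, seed=1)
    print(f"identity {t:.2f}: {cs.n_clusters:3d} clusters, pH p = {p:.3f}")
```

prints

```
identity 1.00:  32 clusters, pH p = 0.001
identity 0.97:  31 clusters, pH p = 0.001
identity 0.95:  30 clusters, pH p = 0.001
identity 0.90:  22 clusters, pH p = 0.001
identity 0.85:  20 clusters, pH p = 0.001
identity 0.80:  16 clusters, pH p = 0.001
identity 0.70:   9 clusters, pH p = 0.001
```

The cluster count falls as the identity radius widens (32 dereplicated
sequences collapse to 9 deep lineages at 70%), and the simulated pH niche
structure is detected at every taxonomic scale: `p = 0.001` is the smallest
p-value attainable with 999 permutations. A full run — clustering, the
coherence table over all 29 factors, trees, delineation, preferences,
ancestral states, congruence — is one call:

```
nichephylo run --config config.yaml     # or: nichephylo --help
```

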