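# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `nichephylo`, in the order the pipeline runs.

## Synthetic study generator

The generator produces a dual-marker soil survey with known truth. Its
defaults are the study design the pipeline targets: 46 soils spanning pH
3.5–8.5, ~592 bp amplicons, on the order of 10⁴ reads per soil per marker,
and 32 dereplicated taxa.

**Trees.** Topologies are Yule (random splits), with iid unit-mean
exponential branch lengths; the analysis is topology-agnostic, so a more
elaborate diversification model would add nothing testable. The two marker
trees share one topology up to a configurable number of subtree-prune-
regraft (SPR) edits (`spr_moves`, default 0). An SPR regraft is forbidden
onto the pruned edge, its parent edge, its sibling edge, and — when the
pruned node hangs just below the root — the root's other child edge, because
all of those are the same unrooted edge and would leave the topology
unchanged. Tip labels are assigned in *random* order: labelling tips in
traversal order would make label adjacency track topology in every tree,
which silently fabricates congruence between independently simulated trees
(we found exactly this as an inflated type-I error of the congruence test
and fixed it; the calibration suite guards it).

**Sequences.** Jukes–Cantor evolution along each tree, substitution
probability per site `(3/4)(1 − e^(−4rb/3))` on a branch of length `b` at
rate `r` (expected substitutions/site/branch-length unit). Defaults
`r₁₆S = 0.015` and `r_amoA = 0.06` make the functional marker ~4× faster,
so the 16S identity ladder collapses earlier than the amoA ladder — the
same diversity asymmetry the two real markers show. Substitutions only; no
indels (sequences are generated aligned).

**Environment.** pH is uniform on [3.5, 8.5]. Every other factor is drawn
through a Gaussian copula on the pH normal scores with Pearson correlation
`2·sin(πρ_s/6)`, which targets a requested Spearman `ρ_s` exactly in
expectation; the marginal is a monotone map onto the factor's range, so
`ρ_s = ±1` is achieved exactly. Default ranges and correlations sketch UK
mineral-to-organic soils (organic matter, water content, C:N falling with
pH; Zn the only metal tracking pH); the 29-factor vocabulary matches the
environmental table schema. Vegetation is assigned from pH/organic-matter
bands. For experiments needing a single driver, pass a factor spec with all
correlations zero.

**Abundances.** Tip pH optima evolve by Brownian motion from a root state
at the gradient midpoint (6.0) with rate `bm_sigma2` (pH²/branch-length
unit); the expected relative abundance of taxon *i* in soil *s* is the
Gaussian niche response `∝ exp(−(pH_s − opt_i)²/(2w²))` with niche width
`w = 0.5` pH units; counts are multinomial at the configured depth. The
default `bm_sigma2 = 0.8` was calibrated once so that tip optima span the
full acidophile-to-alkalinophile range at typical tree height (marginal sd
≈ 2 pH units) and the end-to-end recovery property below holds; it was not
revisited afterwards.

**What the generator does not emulate.** 454 error profiles, chimeras,
indels, primer bias, spatial/temporal structure, and competition beyond the
shared multinomial denominator. Tests passing on this generator show the
*estimators* behave as designed under the model the analysis assumes; they
do not validate the model against real soil data.

## Identity and clustering

Pairwise identity is defined exactly, because published greedy-clustering
tools vary by version: optimal global alignment with match +1, mismatch −1,
gap −2 (linear), identity = identical columns / alignment columns after
stripping terminal-gap columns. Co-optimal alignments can differ in
identity, so the function canonicalises its argument order to be symmetric
by construction. Greedy clustering processes records by decreasing total
read count (ties: lexicographic id, so permuting equal-count input changes
nothing) and joins the *first* centroid at or above the threshold —
matching the classic greedy picker; a best-match variant is a flag. The
cluster count is empirically non-increasing along the 100→70% ladder on
all inputs we generate; this is a property test, not a theorem (greedy
first-match clustering admits contrived counterexamples).

The soil read floor (`min_reads_per_soil`, default 1000) is exposed as a
parameter because real surveys drop low-coverage samples without always
stating the rule.

## CCA and the coherence table

`cca_fit` implements ter Braak's algorithm directly (chi-square residuals,
row-mass-weighted least squares, SVD of the fitted matrix); it was verified
at development time to reproduce vegan's `cca` eigenvalues and
`anova.cca`'s pseudo-F to machine precision, and the test suite holds it
against an explicit dense-algebra oracle at 1e-8. Degenerate inputs error
early: constant constraint columns, rank-deficient designs (the collinear
columns are named), all-zero rows.

Each factor is tested *marginally* (one single-constraint CCA per factor):
the coherence table reports one p per factor per scale and no conditioning
is described for the original analysis; a partial-CCA hook is the natural
extension point. Missing factor values are dropped pairwise per test.
Vegetation is dummy-coded with the most frequent level as reference. The
permutation unit is the soil; p-values use the add-one convention
`(b+1)/(m+1)`, so 0.001 is the floor at 999 permutations. Permutation
seeds depend on threshold and factor (not on the data-set name), so
identical data sets yield identical columns.

## Trees, supports, PCoA

Neighbor joining (Saitou–Nei) is written against the package's own tree
container, with negative branch-length estimates clamped to zero and
midpoint rooting by default (outgroup rooting is a parameter); the test
suite cross-checks the topology against scikit-bio's independent NJ and
verifies exactness on additive matrices. Bootstrap supports are the
fraction of column-resampled replicates containing each bipartition
(trivial bipartitions excluded). They occupy the same [0, 1] slot as
Bayesian posterior node supports and feed the same >0.70 delineation rule,
but they are *not* posterior probabilities; on desk-scale alignments they
are typically more conservative.

PCoA is Gower double-centering of −½D² with eigendecomposition; axes with
eigenvalue > 1e-8 are kept and scaled by √eigenvalue; negative eigenvalues
(patristic matrices are generally non-Euclidean) are dropped with a logged
warning of the dropped mass. No Lingoes/Cailliez correction is applied —
this matches the simplest published ParaFit variant; a correction flag is
the obvious extension.

## Clade delineation and preferences

A cluster is a *maximal* clade in preorder from the root whose tips all
exceed the identity threshold (>0.90) pairwise and whose root support
exceeds the support threshold (>0.70); on emission the traversal stops
descending, so clusters are disjoint by construction, and tips never
captured become unplaced singletons. An undefined support (the tree root)
counts as 1.0. The original delineation admits manual exceptions ("in most
cases"); here exceptions are explicit — an override list of tip sets,
logged and flagged `rule_relaxed`.

Preferences are abundance-weighted means of each factor over soils
(weights = the cluster's relative abundance per soil); a cluster is
"abundant" above 5% of the data set's reads. pH classes use boundaries
5.5/7.0 (closed lower bound on neutrophilic); the boundaries are parameters
because no numerical definition exists for the acidophile/neutrophile/
alkalinophile usage over a 3.5–8.5 soil gradient. The pH response curve is
a degree 1–3 polynomial chosen by AICc (smallest exactly-fitting degree
wins when residuals vanish, since AICc on a zero residual is meaningless);
a polynomial replaces a penalised smoother deliberately — it affects only
the plotted curve, never the statistics.

**A knife-edge property worth knowing.** Under the generator's own
conditions (w = 0.5, depth 10⁴, 30–40 soils), the abundance-weighted mean
pH of an abundant cluster recovers the mean true optimum of its member tips
within 0.5 pH units in ≈90% of cluster instances — and this rate saturates
near 90% for any realistic `bm_sigma2`. The residual misses are systematic,
not sampling noise: (i) relative abundances are compositional, so a
mid-gradient cluster's share keeps rising toward a gradient edge whenever
competitor mass thins there, biasing the weighted mean outward by a few
tenths of a pH unit; and (ii) a cluster whose true optimum lies outside the
sampled pH window can only be estimated at the window edge. Both effects
apply verbatim to real surveys; weighted-mean preferences near the ends of
an environmental gradient should be read as bounded toward the interior.

## Brownian-motion ancestral states

The root state is the GLS estimate `(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹x` with `V` the shared
path-length matrix; every internal node's state is the same estimator with
the tree re-rooted there; `σ²` is the ML estimate (divisor n, the classical
phylogenetics default rather than REML). All of it is computed by a
two-pass message-passing scheme (Felsenstein pruning up, a complementary
pass down, precision-weighted combination at each node) in linear time; the
test suite pins it to the explicit-matrix GLS at 1e-8 and checks affine
equivariance. Zero-length branches are set to 1e-9 (the polytomy limit)
with a logged warning. Node variances `(Σ precision)⁻¹·σ̂²` are returned;
no confidence intervals are drawn. Tips flagged as culture/reference
sequences are pruned before reconstruction, preserving path lengths among
the remaining tips.

## Congruence

Tier-1 links join clusters sharing a reference organism (many-to-one
allowed — several ribosomal clusters may anchor to one functional-gene
cluster); a reference appearing in two clusters of the same marker is an
error, not a warning. Tier-2 links greedily match the remaining *abundant*
clusters by |Δ log read fraction| within log(1 + 0.25), subject to
|Δ mean pH| ≤ 0.5, ties broken by smaller pH gap, one link per cluster.
Both tolerances are explicit parameters because no numerical definition of
"similar abundance and similar pH specialisation" exists.

The global ParaFit statistic is `trace(DᵀD)`, `D = Cᵀ A B`; the null
permutes the row order of `A` (the standard global null); the test is
one-tailed upper, since shared history inflates the statistic; p uses the
add-one convention. Calibration (200 null simulations of independent tree
pairs, 199 permutations) sits at the nominal rate; perfect congruence with
999 permutations reaches the floor p = 0.001.

## Problem sizes

Defaults used by the test and acceptance suites — 16–64 tips, 250–300 bp,
30–46 soils, 10⁴ reads/soil, 100 replicates for recovery/coverage rates,
199–999 permutations — are the sizes at which every claimed property is
measured; all are parameters, and all scale up without code changes.

## Known limitations

- NJ + bootstrap is a stand-in for Bayesian tree inference: same output
  structure, different uncertainty semantics.
- Identity is computed by exact global alignment with one fixed scoring
  scheme; no k-mer prefilter (inputs are desk-scale by design).
- The coherence table's marginal tests inherit the collinearity of the
  environmental factors; the Spearman matrix is provided precisely so
  readers can see which factors travel together.
- Greedy cluster-count monotonicity across thresholds is asserted
  empirically, not proven.
- No chimera/recombinant screening: the filter hook is a pass-through
  marking where such a step would sit.
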