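# Methods

This note documents the statistical machinery implemented in `hostphylo`,
its assumptions, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Setting

The data model is a multi-site survey of insect herbivores (caterpillars)
on woody host plants. Each site contributes: a dated subphylogeny of its
host species (branch lengths in millions of years, My), a community table
of per-species summed leaf areas (m², the availability measure), and
individual-level interaction records (site, tree individual, plant
species, herbivore species, feeding guild, count). Guilds form a closed
vocabulary: `exposed` (free-living on foliage) and `shelter` (leaf
rollers, tiers, webbers). Analyses run at the plant-species level; tree
individuals are provenance only, except as the random-effect grouping of
the model stage.

Herbivore species with fewer than `min_n = 3` total individuals are
excluded before any analysis — singletons and doubletons are as likely to
be stray records as real interactions, and they would make specialization
scores degenerate. The filter is applied within each site by default,
because each site has an essentially disjoint species pool and is analyzed
as its own dataset; a pooled variant is available (`per_site=False`).

## Tree metrics

Patristic distance is the sum of branch lengths on the tip-to-tip path.
Evolutionary distinctiveness uses fair proportions: each branch's length
is divided equally among its descendant tips and summed along each tip's
root path. ED therefore conserves total branch length (the basis of a
core invariant test). High ED = no close relatives locally = high
*phylogenetic isolation* (PI). Polytomies are handled without resolution;
zero-length branches are legal (a tip with an all-zero root path gets
ED = 0 and a log warning); a root edge, when the Newick carries one, is
shared equally by all tips. Trees are taken as rooted as written — no
midpoint re-rooting. Pruning to a site pool collapses unary nodes and
sums their lengths, so pairwise distances among retained tips are exactly
those of the master tree.

## Assemblage similarity

Jaccard (incidence), Bray–Curtis similarity (1 − dissimilarity) and
Morisita–Horn. Similarity, not dissimilarity, is the exposed quantity:
the hypothesis under test is a *negative* correlation of assemblage
overlap with phylogenetic distance. Pairs in which either assemblage is
empty after filtering are excluded and counted, never coerced to zero —
zero would conflate "no data" with "observed no overlap".

## Stratified Mantel test

Sites share almost no plant or herbivore species, so a single pooled
distance matrix would manufacture meaningless between-site pairs. The
protocol instead: (1) build the D/S matrix pair per site; (2) vectorize
strictly-lower triangles in row-major order and concatenate across sites;
(3) observed statistic = Pearson r of the concatenated vectors;
(4) permutation null: independently per site, one uniform random
relabeling applied simultaneously to rows and columns of D (S fixed) —
the standard Mantel null, which preserves within-matrix structure —
re-concatenate and recompute r; (5) p = (1 + #extreme) / (1 + n_perm)
(add-one convention, so the minimal p is 1/(n_perm+1)).

Defaults: `alternative="less"` (the decay hypothesis; both tails are
available), 9,999 permutations, raw concatenation. Per-site z-scoring of
the vectors and Spearman correlation exist behind flags for sensitivity
analysis only. With a single site the procedure reduces exactly to the
classic simple Mantel test, which the tests verify against a naive
independent implementation sharing the permutation stream. Partial Mantel
tests and cross-site mega-matrices are deliberately out of scope.

## DSI and DSI*

For herbivore i with N_i individual records distributed over hosts with
counts n_h, the observed MPD is the individual-based mean pairwise
distance: with count vector c, MPD = cᵀDc / (N(N−1)) — all unordered
pairs of individuals, same-host pairs contributing 0. The null
re-allocates the same N_i individuals to hosts drawn with replacement
from the full site community with probability proportional to leaf area
(999 iterations by default; sd uses the n−1 denominator). Then

    DSI_i = −(MPD_i − mean(Null_i)) / sd(Null_i).

The sign flip makes larger values mean *more specialized* (hosts more
closely related than availability predicts), so that the index's stated
anchors hold: +1 is maximum specialization, −1 maximum generalization.

Standardization limits: DSI_lim_max corresponds to MPD = 0 (monophagy);
DSI_lim_min to the allocation of N_i individuals maximizing MPD, found by
exhaustive enumeration of compositions when their number is ≤ 10⁵ and
otherwise by a greedy local search (single-individual moves, hill
climbing from an even split across the two most distant hosts), flagged
`approximate_lim`. DSI* divides positive DSI by DSI_lim_max and negative
DSI by |DSI_lim_min|; clamping to [−1, 1] happens only under approximate
limits, with a warning. Crucially, one null distribution per species is
shared by the score and both limits, which makes the monophage identity
DSI* = 1 exact rather than Monte-Carlo-approximate. Species occurring at
several sites get independent per-site scores. Per-plant mean
specialization is the unweighted mean DSI* of the (post-filter) species
recorded on the plant, per guild scope.

Options: observed MPD can alternatively weight utilized-host pairs by
community leaf area (`weighting="host_leaf_area"`); the null can draw
distinct hosts without replacement (`mode="distinct_hosts"`,
experimental). Both defaults — individual-based weighting and
with-replacement draws — are chosen for internal consistency: the null
allocates individuals, so the observed statistic should be
individual-based too.

Degenerate cases (single-host communities, N_i < 2) yield flagged NaN
scores, never a silent 0.

## Model stage

Responses per plant species × guild: abundance (row sum of the assemblage
matrix; natural log, zero rows dropped for this response only), density
(abundance / leaf area; log(x+1), zeros retained), richness (count of
herbivore species; untransformed), and mean DSI* (untransformed). Fixed
factors: PI, √leaf area, site, guild, plus the guild×site interaction
when both main effects are present. Random intercept: host tree species.
The candidate set is all 16 additive subsets plus 4 interaction variants.

Fits are maximum likelihood, not REML, because AICc comparisons span
different fixed structures. k counts the fixed coefficients (incl.
intercept) plus the random-intercept and residual variances.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights normalize
exp(−ΔAICc/2). Selection: among models with ΔAICc ≤ 2, the fewest
parameters; ties break by AICc, then a fixed spec ordering, so selection
is deterministic. The selected model is tested against the intercept-only
null by a chi-square likelihood-ratio test on identical rows. Optimizers
occasionally stall when a variance component sits on the boundary; the
fit walks a ladder of methods (lbfgs, bfgs, powell, nm) and flags fits
that still fail, which are excluded from ranking with a warning.

Post hoc guild differences per site are Wald contrasts of the fixed
effects with Holm adjustment across sites. A Tukey HSD is not
well-defined for this mixed-model setting without additional
multivariate-t machinery, so the Holm–Wald procedure is used and labeled
as such in the output.

A pre-check regression (OLS of √leaf area on PI with site as covariate)
quantifies confounding between the two resource-level predictors before
they are interpreted jointly.

## Synthetic data generator

Per site: a pure-birth tree rescaled to depth 100 My (the simulator's
final sister pair is separated by extending all pendant edges by the
waiting time to the next speciation, keeping the tree ultrametric); leaf
areas lognormal(ln 150, 1) m², multiplied by exp(ρ·z(ED)); each herbivore
species draws a focal host ∝ leaf area, a guild-specific niche breadth σ
(My) and a lognormal(2.5, 1.2) total abundance, and places its
individuals multinomially with weights leaf_area_j · exp(−d(focal, j)/σ).
The exponential kernel was preferred over a Gaussian: one parameter, and
a heavy enough tail to produce intermediate specialists rather than a
monophage/generalist dichotomy. σ → 0 gives strict monophages; σ = ∞
makes host use track availability exactly, which is the DSI null — such
species have expected DSI 0, a calibration property the tests exercise.

Defaults mirror a three-temperate-forest study design at reduced sampling
depth: sites of 8/20/15 host species, exposed/shelter richness of
23+13 / 28+22 / 27+20 species, leaf-area scale ~150 m² per species, and
σ_niche = 80 My (exposed) vs 30 My (shelter), making shelter builders the
more specialized guild; ρ = −0.6 couples isolation negatively to leaf
area with PI explaining roughly a fifth of leaf-area variance, the
magnitude reported for real temperate forest communities. These sizes
keep a full end-to-end run under a minute while leaving every downstream
pattern detectable.

What the generator does *not* emulate: phenology and seasonality,
multi-year turnover, parasitism, within-plot spatial structure,
herbivore phylogeny, and observation error in leaf-area estimation.
Passing recovery tests on these data therefore demonstrates the
pipeline's correctness and power under idealized sampling, not the
field-data effect sizes.

## Determinism and numerics

All stochastic stages take explicit seeds; hierarchical
`numpy.random.SeedSequence` substreams give per-site and per-species
reproducibility that is stable under re-ordering. Distance matrices are
validated (symmetric to 1e-9, hollow, non-negative) and symmetrized
before use. Pearson correlations are computed on centered vectors with a
shared permutation stream so the single-site case is bit-comparable to a
naive Mantel implementation. The pipeline bundle (CSV + sorted-key JSON,
no timestamps) is byte-reproducible under a fixed config.

## Known limitations

* The greedy MPD maximizer is a local search; it matches exhaustive
  enumeration on all tested instances but carries no optimality proof,
  hence the `approximate_lim` flag and the clamping rule.
* MixedLM variance components on the boundary (singular random-effect
  covariance) make some candidate fits fragile; non-converged fits are
  dropped from ranking rather than repaired.
* p-values from permutation tests are bounded below by 1/(n_perm+1);
  with the default 9,999 permutations that is 1e-4.
* The stratified Mantel test inherits the general caveats of Mantel
  tests (non-independence of pairs; power depends on the form of the
  distance–similarity relationship).
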